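# ppmspect

Chemometrics for 1D ¹H-NMR urine metabolomics in small case–control
cohorts: spectral alignment, uniform 0.0025-ppm binning with water/TSP
exclusion, total-area normalization, Pareto-scaled PCA, leave-one-out
cross-validated classification (Random Forest / gradient boosting / SVM,
on scaled bins or on 3–10 leading principal components), and
loading-threshold discovery of the ppm regions that drive the separation,
annotated to metabolites. A synthetic cohort generator with planted
group effects makes the whole chain testable without access to clinical
spectra.

The package is aimed at metabolomics analysts who have a spectra matrix
(ppm grid × samples) and a group label per sample — here *preterm* vs
*term* — and want a reproducible, leakage-aware version of the classic
two-phase workflow: an unsupervised phase (PCA of the mean-centered,
Pareto-scaled bin table, `x'_{ij} = (x_{ij} − x̄_j)/√s_j`) and a supervised
phase (LOOCV classification with confusion rates TPR/TNR/FPR/FNR, accuracy
and F1, positive class = preterm), followed by feature selection on the PCA
loadings: a bin enters the candidate set at threshold *t* when
`max_{c≤3} |p_{jc}| ≥ t`, and contiguous candidate bins merge into reported
ppm ranges.

## Worked example

```python
from ppmspect import (
    CohortConfig, simulate_cohort, preprocess_pipeline,
    fit_pareto_pca, loocv_on_pcs, sweep_pc_count, build_region_set,
)

# 49 preterm + 18 term urine spectra with a planted 1.5x contrast on
# citrate, creatinine CH2, fumarate and hippurate
spectra, labels = simulate_cohort(CohortConfig(seed=1))

binned, shifts = preprocess_pipeline(spectra)   # align, bin, normalize
print(binned.matrix.shape)

row = loocv_on_pcs(binned, labels, "RF", k=3, seed=1)
print(round(row.accuracy, 3), round(row.f1, 3))

pca = fit_pareto_pca(binned.matrix, 3)
regions = build_region_set(pca, binned.bin_edges, threshold=0.02)
print(sorted(regions.annotated_metabolites))
```

prints

```
(67, 3360)
0.851 0.9
['citrate', 'creatinine_CH2', 'fumarate', 'hippurate']
```

i.e. the default scheme retains 3360 bins (3600 bins on 0.5–9.5 ppm minus
the 240 covering the water region), the Random Forest classifies 85.1% of
held-out samples correctly from the first three fold-internal principal
components, and the 0.02 loading threshold recovers regions annotated to
all four planted metabolites.

The same pipeline runs from the shell on real or simulated data:

```sh
ppmspect simulate --seed 1 --out cohort
ppmspect classify cohort_spectra.tsv cohort_samples.tsv --sweep --out sweep.json
ppmspect regions cohort_spectra.tsv --out regions.tsv
ppmspect run --seed 1 --out results/   # full bundle in one command
```

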