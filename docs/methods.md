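# Methods

`ppmspect` reimplements, as a tested library and CLI, the standard urine
¹H-NMR chemometrics workflow used to contrast two clinical groups (here
labelled *preterm* and *term*): spectral alignment, uniform binning with
solvent-region exclusion, total-area normalization, Pareto-scaled PCA,
leave-one-out cross-validated classification, and loading-threshold
discovery of discriminating spectral regions. Because cohort NMR data of
this kind are rarely shareable, the package also ships a synthetic cohort
generator that emulates the statistical structure the analysis assumes, so
that every downstream stage is exercised end to end.

## The synthetic cohort generator

A spectrum is simulated as

```
I(δ) = dilution · Σ_m Σ_l c_m · a_{m,l} · L(δ; μ_{m,l} + j_m, γ) + baseline + ε(δ)
```

clipped at zero, where `L` is a peak-normalized Lorentzian (the natural NMR
lineshape) with half-width-at-half-maximum `γ` (default 0.002 ppm, so a line
spans several 0.0025-ppm bins), `c_m` the metabolite concentration and
`a_{m,l}` fixed multiplet line weights. The default library holds the four
discriminating metabolites at their acid-pH positions — citrate (AB quartet
around 3.13 ppm), creatinine CH₂ (4.28 ppm), fumarate (6.80 ppm), hippurate
(aromatic multiplet, 7.6–7.8 ppm) — plus creatinine CH₃ (3.05 ppm, a
conventional placement, flagged as an assumption) and six non-discriminating
background metabolites (lactate, alanine, dimethylamine, glycine, urea,
formate) that make region selection nontrivial.

Per-sample nuisance structure, with defaults chosen once to emulate a
realistic cohort of this size and then frozen:

| parameter | default | role |
|---|---|---|
| `n_preterm` / `n_term` | 49 / 18 | the study's group sizes |
| `group_effects` | 1.5× on the four discriminating metabolites (preterm up) | the planted contrast |
| `shift_jitter_sd` | 0.005 ppm (≈2 bins) | per-sample pH shift; exercises alignment |
| `jitter_idiosyncratic_frac` | 0.2 | per-metabolite deviation from the common pH shift |
| `concentration_cv` | 0.2 | between-subject biological variability (unit-mean log-normal) |
| `dilution_range` | (0.7, 1.3) | urine dilution; exercises total-area normalization |
| `noise_sd` | 0.001 | additive detector noise (per-point SNR ≈ 1000 vs unit peaks) |
| `baseline_amplitude` | 0 | optional broad Gaussian bump; 0 keeps exactness tests exact |
| `grid` | 36,001 points on 0.5–9.5 ppm | 10 raw points per 0.0025-ppm bin |

Two of these deserve comment. First, the chemical-shift jitter is modelled
as a *common* per-sample shift (pH is a property of the sample) plus a small
idiosyncratic per-metabolite deviation: if the jitter were fully independent
per metabolite, no rigid alignment could ever correct it and classification
accuracy would be capped by an artifact of the generator rather than by the
planted effect size. Second, between-subject concentration variability is
what keeps the problem honest in the other direction — without it the
1.5× contrast is separable almost perfectly. With these defaults the
Random-Forest LOOCV accuracy on 3 principal components lands in the
0.80–0.95 band across seeds, qualitatively matching what such cohorts
report, and a strong version of the effect (3×, low noise) is perfectly
separable.

The generator does **not** emulate: J-coupling evolution or any
quantum-mechanical spin physics (multiplets are frozen line patterns),
field-strength effects, water/TSP resonances (their regions are excluded
downstream anyway), peak-shape distortions, correlated metabolite panels, or
covariate structure (sex, age). Passing tests on synthetic cohorts therefore
demonstrate that the *pipeline machinery* behaves correctly under the
assumed statistical structure — not that real preterm/term urine is
separable at any particular accuracy.

Determinism: each sample receives a child RNG stream spawned from the cohort
seed, and the per-sample draw order is fixed (jitter, concentration factors,
dilution, noise), so matched-seed cohorts that differ in a single parameter
stay paired draw-for-draw — the dilution-invariance test depends on this.

## Preprocessing

* **Alignment** — a rigid per-sample shift by an integer number of grid
  steps, chosen to maximize cross-correlation with the pointwise-median
  spectrum within ±`max_shift_ppm` (default 0.02 ppm). Vacated edge points
  are filled with the edge value; shifts at the window edge are reported
  with a warning. A `max_shift_ppm` above 10% of the grid span is rejected
  as pathological. Segment-wise alignment exists behind a flag but is off by
  default: the transparent rigid shift is the baseline choice.
* **Binning** — half-open bins `[lo, hi)` of width 0.0025 ppm tiling
  0.5–9.5 ppm exactly. The bin value is the trapezoidal integral of the
  intensity over the bin divided by the width (a mean intensity, invariant
  to grid oversampling); edges that fall between grid points are handled by
  interpolating the cumulative integral. A bin is dropped on *any* overlap
  with an excluded region (water 4.6–5.2 ppm; TSP −0.5–0.5 ppm, which lies
  outside the binned range) — the conservative reading, kept as a documented
  constant. The default scheme retains exactly 3360 of 3600 bins.
* **Normalization** — each row divided by its own total, *after* exclusion,
  so the retained spectral area is the denominator and the water region
  cannot dominate it; a pre-exclusion variant exists for sensitivity
  analysis. With additive detector noise the cancellation of dilution is
  exact only up to the noise-floor share of the total area; the test suite
  bounds this residual from the error model rather than asserting exact
  equality.

## Chemometrics

Columns are mean-centered and Pareto-scaled, `x' = (x − mean)/√sd`, with the
sample standard deviation (n−1); near-constant columns (sd < 1e-12) are
centered only. Pareto scaling is the conventional compromise for NMR bins:
it damps the dominance of intense peaks without inflating noise the way full
autoscaling does.

PCA is the SVD of the scaled matrix; loadings are the top-k right singular
vectors under a deterministic sign convention (largest-magnitude entry of
each loading made positive), which makes loading thresholds and reports
reproducible. Score-space outliers (Mahalanobis distance over the first 3
PCs beyond the χ²₃ 0.975 quantile) are reported, never removed — the
pipeline flags, a human decides.

## Classification

Three classifiers with fixed hyperparameters (determinism and
comparability, not tuning): Random Forest (500 trees, √p features per
split), gradient boosting (100 stages, depth 3, learning rate 0.1), and an
RBF-kernel SVM (C = 1, γ = 1/(p·var)). The positive class is *preterm*.
LOOCV predicts each sample from a model trained on the other n−1; per-fold
model seeds derive deterministically from (global seed, fold index), so a
sample's prediction does not depend on how the other samples are ordered.

PC-score features come in two leakage modes. In `strict` (the default) the
Pareto scaling and PCA are refit on each fold's n−1 training rows and the
held-out row is projected through the training transform — the held-out
sample never shapes its own feature space. In `global` the transform is fit
once on all rows, the way pipelines that run PCA before cross-validation
behave; it is retained as an explicit compatibility mode because published
analyses of this design usually do not state which they did. At large n with
strong signal the two agree closely; at n = 67 `global` is mildly
optimistic. The top-k property of the SVD means fold transforms are computed
once at the largest k and sliced, so the 3–10-component sweep (3 models × 8
k values) costs one set of fold PCAs, not 24.

Sweep ties break toward fewer components, then model order RF < GBM < SVM.
RF importance of PCs is permutation importance (mean accuracy drop over 50
shuffles, clipped at 0, with Monte-Carlo sd); impurity-based importance is
available behind a flag. Samples are put in canonical order before the fit
so reported importances are invariant to input row order.

Cohort-characteristic comparisons use Welch's unpaired t-test from summary
statistics (continuous) and Pearson's χ² without continuity correction on
2×2 tables (categorical).

## Region selection

A bin is selected at threshold t if its absolute loading on *any* of the
first three PCs reaches t (per-PC selections are kept in the output for
traceability). Selected bins merge into contiguous ppm ranges, bridging up
to `gap_tol_bins` (default 2, ≤0.005 ppm) unselected bins — a multiplet
split by one noisy bin is one region — but never across an exclusion gap.
Ranges are annotated with every metabolite whose assignment point or
interval overlaps them; the default assignment table holds the four
discriminating assignments, with citrate recorded as its quartet footprint
(3.07–3.19 ppm) since the selected bins sit at the lines, not the center.
The threshold ladder {0.1, 0.05, 0.025, 0.02} is applied on raw loading
magnitudes of the unit-norm loading vectors (no rescaling by explained
variance). Selections are nested down the ladder; note that *region counts*
need not be monotone, because newly selected bins can fuse two regions.

On noise-only data the procedure still selects something — PCA of noise has
large loadings somewhere — and no null calibration is claimed; the tests
only require the selected bandwidth to be a stable, bounded fraction of the
spectrum under null effects.

## Numerical and design choices

* Bin edges and exclusion overlap use a 1e-9 tolerance; grid uniformity is
  validated to 1e-9 relative.
* Sample sd uses n−1 throughout.
* F1 with zero predicted positives is defined as 0, with a warning.
* The spectra-matrix text format round-trips at 9 significant digits.
* Internal ppm orientation is always ascending; readers normalize descending
  (display-convention) inputs, including JCAMP-DX with FIRSTX > LASTX.
* The JCAMP-DX reader covers AFFN-encoded 1D XYDATA/NTUPLES records only;
  compressed (DIF/DUP) forms and vendor FID directories are out of scope.

## Problem sizes used in the checks

The test suite and the acceptance script run the full 67-sample, 36k-point,
3360-bin pipeline for the frozen-fixture classification, the 3-model PC
sweep, the 20-seed region-recovery check and the 200-permutation null
control; generator-level statistical properties (null symmetry, planted
monotonicity) use coarser grids and 10–50 Monte-Carlo seeds. These sizes are
the package's own choices for routine verification; all scale up by
argument.

## Known limitations

* The rigid alignment cannot correct metabolite-specific shift differences;
  segment-wise alignment is available but unvalidated against references.
* `global` leakage mode is optimistic at small n and is not the default.
* The synthetic generator's gap between simulation and real urine (see
  above) means accuracy figures on synthetic cohorts characterize the
  method, not the biology.
* Region annotation is purely positional; overlapping metabolites in
  crowded regions will co-annotate.
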