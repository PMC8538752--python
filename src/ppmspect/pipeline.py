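"""End-to-end orchestration: simulate/load → preprocess → PCA → classify → regions.

The pipeline is configured by a single flat mapping with namespaced keys
(``synth.*``, ``preprocess.*``, ``pca.*``, ``classify.*``, ``regions.*``
plus global ``seed`` and paths); unknown keys are rejected, and the config
is echoed verbatim into every report so that each number in the bundle can
be replayed. Also houses the participant-flow accounting helper used for
cohort reporting.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .chemometrics import fit_pareto_pca, flag_score_outliers
from .classify import (
    MODEL_ORDER, loocv, loocv_on_pcs, pareto_scale, rf_pc_importance, sweep_pc_count,
)
from .preprocess import BinSpec, preprocess_pipeline
from .regionselect import DEFAULT_THRESHOLDS, run_threshold_ladder
from .spectra_io import (
    SampleTable, Spectrum, read_sample_table, read_spectra_matrix, write_report,
)
from .synthdata import CohortConfig, default_metabolite_library, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


_KNOWN_KEYS = {
    "seed", "simulate", "spectra_path", "metadata_path", "out_dir",
    "synth.n_preterm", "synth.n_term", "synth.shift_jitter_sd",
    "synth.dilution_low", "synth.dilution_high", "synth.noise_sd",
    "synth.baseline_amplitude", "synth.grid_points", "synth.effect_ratio",
    "preprocess.align", "preprocess.max_shift_ppm", "preprocess.bin_width",
    "preprocess.ppm_min", "preprocess.ppm_max",
    "preprocess.normalize_before_exclusion",
    "pca.components",
    "classify.models", "classify.k_min", "classify.k_max", "classify.leakage_mode",
    "regions.thresholds", "regions.n_pcs", "regions.gap_tol_bins",
}


def validate_config(config: Mapping) -> dict:
    """Reject unknown keys; return a plain dict copy."""
    unknown = sorted(set(config) - _KNOWN_KEYS)
    if unknown:
        raise PipelineError(f"unknown config key(s): {unknown}")
    return dict(config)


@dataclass(frozen=True)
class FlowChart:
    """Ordered participant-flow accounting: eligible pool minus per-stage removals."""

    initial_eligible: int
    removals: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.initial_eligible < 0:
            raise PipelineError("initial_eligible must be nonnegative")
        for label, count in self.removals:
            if count < 0:
                raise PipelineError(f"negative removal count at stage {label!r}")


def cohort_flow(flow: FlowChart) -> tuple[list[tuple[str, int]], int]:
    """Running subtraction through the flow chart.

    Returns (per-stage remaining counts, final enrolled count); a negative
    remainder at any stage is an error.
    """
    remaining = flow.initial_eligible
    stages: list[tuple[str, int]] = []
    for label, count in flow.removals:
        remaining -= count
        if remaining < 0:
            raise PipelineError(
                f"stage {label!r} removes {count}, more than the {remaining + count} remaining")
        stages.append((label, remaining))
    return stages, remaining


def _cohort_config_from(config: Mapping, seed: int) -> CohortConfig:
    base = CohortConfig(seed=seed)
    kwargs = {}
    if "synth.n_preterm" in config:
        kwargs["n_preterm"] = int(config["synth.n_preterm"])
    if "synth.n_term" in config:
        kwargs["n_term"] = int(config["synth.n_term"])
    if "synth.shift_jitter_sd" in config:
        kwargs["shift_jitter_sd"] = float(config["synth.shift_jitter_sd"])
    if "synth.noise_sd" in config:
        kwargs["noise_sd"] = float(config["synth.noise_sd"])
    if "synth.baseline_amplitude" in config:
        kwargs["baseline_amplitude"] = float(config["synth.baseline_amplitude"])
    if "synth.dilution_low" in config or "synth.dilution_high" in config:
        kwargs["dilution_range"] = (
            float(config.get("synth.dilution_low", base.dilution_range[0])),
            float(config.get("synth.dilution_high", base.dilution_range[1])))
    if "synth.grid_points" in config:
        kwargs["grid"] = (base.grid[0], base.grid[1], int(config["synth.grid_points"]))
    if "synth.effect_ratio" in config:
        r = float(config["synth.effect_ratio"])
        kwargs["group_effects"] = {m: r for m in base.group_effects}
    return base.with_(seed=seed, **kwargs)


def run_pipeline(config: Mapping, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis and return the report bundle.

    The bundle contains: preprocessing dimensions and per-sample alignment
    shifts, the PCA summary with flagged (never removed) score outliers,
    metrics rows for all three classifiers on scaled bins and on the best
    PC count, the full PC-count sweep curve, RF importance of the leading
    PCs, and the threshold-ladder region sets. Fully deterministic under
    ``config['seed']``.
    """
    config = validate_config(config)
    seed = int(config.get("seed", 0))
    out_dir = Path(out_dir) if out_dir is not None else None
    t0 = time.time()

    # --- input stage -------------------------------------------------------
    if config.get("simulate", not config.get("spectra_path")):
        cc = _cohort_config_from(config, seed)
        spectra, labels = simulate_cohort(cc, default_metabolite_library())
        logger.info("simulate: %d spectra on %d-point grid", len(spectra), len(spectra[0]))
    else:
        spectra = read_spectra_matrix(config["spectra_path"])
        table = read_sample_table(config["metadata_path"])
        labels = table.labels_for([sp.sample_id for sp in spectra])
        logger.info("load: %d spectra from %s", len(spectra), config["spectra_path"])

    # --- preprocess --------------------------------------------------------
    spec = BinSpec(
        ppm_min=float(config.get("preprocess.ppm_min", 0.5)),
        ppm_max=float(config.get("preprocess.ppm_max", 9.5)),
        bin_width=float(config.get("preprocess.bin_width", 0.0025)),
    )
    binned, shifts = preprocess_pipeline(
        spectra, spec,
        align=bool(config.get("preprocess.align", True)),
        max_shift_ppm=float(config.get("preprocess.max_shift_ppm", 0.02)),
        normalize_before_exclusion=bool(
            config.get("preprocess.normalize_before_exclusion", False)),
    )

    # --- PCA ---------------------------------------------------------------
    n_comp = int(config.get("pca.components", 10))
    n_comp = min(n_comp, len(binned) - 1)
    pca = fit_pareto_pca(binned.matrix, n_comp)
    outliers = flag_score_outliers(pca, n_pcs=3)

    # --- classification ----------------------------------------------------
    models = config.get("classify.models", list(MODEL_ORDER))
    leakage = config.get("classify.leakage_mode", "strict")
    k_min = int(config.get("classify.k_min", 3))
    k_max = int(config.get("classify.k_max", 10))
    k_max = min(k_max, len(binned) - 2)

    scaled_bins, _, _ = pareto_scale(binned.matrix)
    bin_rows = [loocv(scaled_bins, labels, m, seed=seed)[2] for m in models]

    sweep = sweep_pc_count(binned, labels, models=models,
                           k_range=range(k_min, k_max + 1), seed=seed,
                           leakage_mode=leakage)
    best_rows = [
        loocv_on_pcs(binned, labels, m, sweep.best_k, seed=seed, leakage_mode=leakage)
        for m in models
    ]
    importance, importance_sd = rf_pc_importance(
        pca.scores[:, :max(3, min(sweep.best_k, n_comp))], labels, seed=seed)

    # --- regions -----------------------------------------------------------
    thresholds = config.get("regions.thresholds", list(DEFAULT_THRESHOLDS))
    ladder = run_threshold_ladder(
        pca, binned.bin_edges,
        thresholds=[float(t) for t in thresholds],
        n_pcs=int(config.get("regions.n_pcs", 3)),
        gap_tol_bins=int(config.get("regions.gap_tol_bins", 2)),
    )

    bundle = {
        "config": {k: (list(v) if isinstance(v, (tuple,)) else v)
                   for k, v in config.items()},
        "seed": seed,
        "version": __version__,
        "stages": {
            "input": {"n_samples": len(spectra), "n_points": len(spectra[0])},
            "preprocess": {"n_bins": binned.n_bins,
                           "shifts_ppm": np.asarray(shifts).tolist()},
            "pca": {"n_components": n_comp,
                    "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
                    "outlier_samples": [binned.sample_ids[i]
                                        for i in np.nonzero(outliers)[0]]},
        },
        "metrics": [r.to_report_dict() for r in bin_rows + best_rows],
        "sweep": {
            "accuracies": [
                {"model": m, "k": k, "accuracy": acc}
                for (m, k), acc in sorted(sweep.accuracies.items(),
                                          key=lambda kv: (kv[0][1], kv[0][0]))
            ],
            "best_model": sweep.best_model,
            "best_k": sweep.best_k,
            "best_accuracy": sweep.best_accuracy,
        },
        "pc_importance": {"mean": importance.tolist(), "sd": importance_sd.tolist()},
        "regions": [rs.to_report_dict() for rs in ladder],
        "labels": np.asarray(labels).tolist(),
        "wall_time_s": round(time.time() - t0, 2),
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(out_dir / "report.json", bundle)
    return bundle
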