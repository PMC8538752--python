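"""Loading-threshold discovery of discriminating ppm regions.

After PCA of the scaled bin matrix, bins whose absolute loading on any of
the first three principal components reaches a threshold are selected,
merged into contiguous ppm ranges, and annotated with known metabolite
assignments. The threshold ladder {0.1, 0.05, 0.025, 0.02} trades
selectivity for coverage: selections are nested (a higher threshold always
yields a subset), so lowering the threshold only grows the candidate
regions. Thresholds apply to raw loading magnitudes of the unit-norm
loading vectors; no rescaling by explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chemometrics import PCAModel

DEFAULT_THRESHOLDS = (0.1, 0.05, 0.025, 0.02)

_EDGE_TOL = 1e-9


class RegionSelectError(ValueError):
    pass


def default_assignment_table() -> dict[str, tuple[float, float]]:
    """Metabolite → ppm interval assignments (points as zero-width intervals).

    The four discriminating acid-pH assignments: citrate's AB quartet
    straddles its 3.13-ppm center, so its entry is the multiplet footprint;
    creatinine CH₂ and fumarate are singlets; hippurate is the aromatic
    multiplet at 7.6–7.8 ppm.
    """
    return {
        "citrate": (3.07, 3.19),
        "creatinine_CH2": (4.28, 4.28),
        "fumarate": (6.8, 6.8),
        "hippurate": (7.6, 7.8),
    }


def _as_interval(entry) -> tuple[float, float]:
    if np.isscalar(entry):
        return float(entry), float(entry)
    lo, hi = entry
    return float(lo), float(hi)


@dataclass
class RegionSet:
    """Contiguous ppm ranges selected at one loading threshold."""

    threshold: float
    regions: list[tuple[float, float]]
    contributing_pcs: list[tuple[int, ...]] = field(default_factory=list)
    annotations: list[list[str]] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def annotated_metabolites(self) -> set[str]:
        return {m for names in self.annotations for m in names}

    def to_report_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "regions": [
                {"lo_ppm": lo, "hi_ppm": hi,
                 "pcs": list(self.contributing_pcs[i]) if self.contributing_pcs else [],
                 "annotations": self.annotations[i] if self.annotations else []}
                for i, (lo, hi) in enumerate(self.regions)
            ],
        }


def threshold_loadings(model: PCAModel, threshold: float, n_pcs: int = 3) -> np.ndarray:
    """Indices of bins whose max |loading| over the first n_pcs PCs ≥ threshold.

    Monotone: a higher threshold selects a subset.
    """
    if threshold <= 0:
        raise RegionSelectError("threshold must be > 0")
    if n_pcs > model.n_components:
        raise RegionSelectError(
            f"n_pcs={n_pcs} exceeds model rank {model.n_components}")
    mags = np.abs(model.loadings[:, :n_pcs]).max(axis=1)
    return np.nonzero(mags >= threshold)[0]


def per_pc_selections(model: PCAModel, threshold: float, n_pcs: int = 3
                      ) -> dict[int, np.ndarray]:
    """Per-PC selected bin indices (1-based PC keys), kept for traceability."""
    if n_pcs > model.n_components:
        raise RegionSelectError(f"n_pcs={n_pcs} exceeds model rank {model.n_components}")
    return {
        pc + 1: np.nonzero(np.abs(model.loadings[:, pc]) >= threshold)[0]
        for pc in range(n_pcs)
    }


def merge_bins_to_ranges(
    selected: Sequence[int],
    bin_edges: np.ndarray,
    gap_tol_bins: int = 2,
) -> list[tuple[float, float]]:
    """Merge selected bin indices into contiguous ppm ranges.

    Up to *gap_tol_bins* unselected bins may be bridged between consecutive
    selected bins, but never across an exclusion gap (detected as a ppm jump
    larger than the bins' own widths account for). Each range spans from the
    lo edge of its first bin to the hi edge of its last.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        return []
    edges = np.asarray(bin_edges, dtype=float)
    width = float(np.median(edges[:, 1] - edges[:, 0]))
    ranges: list[tuple[float, float]] = []
    start = prev = int(selected[0])
    for idx in selected[1:]:
        idx = int(idx)
        n_skipped = idx - prev - 1
        ppm_gap = edges[idx, 0] - edges[prev, 1]
        contiguous = abs(ppm_gap - n_skipped * width) <= width * 0.5 + _EDGE_TOL
        if n_skipped <= gap_tol_bins and contiguous:
            prev = idx
        else:
            ranges.append((float(edges[start, 0]), float(edges[prev, 1])))
            start = prev = idx
    ranges.append((float(edges[start, 0]), float(edges[prev, 1])))
    return ranges


def annotate_ranges(
    regions: Sequence[tuple[float, float]],
    table: Mapping[str, object] | None = None,
) -> list[list[str]]:
    """Metabolite names per region: a metabolite annotates a region iff its
    ppm point lies inside it or its interval overlaps it."""
    if table is None:
        table = default_assignment_table()
    out: list[list[str]] = []
    for lo, hi in regions:
        names = []
        for name, entry in table.items():
            alo, ahi = _as_interval(entry)
            if ahi >= lo - _EDGE_TOL and alo <= hi + _EDGE_TOL:
                names.append(name)
        out.append(names)
    return out


def build_region_set(
    model: PCAModel,
    bin_edges: np.ndarray,
    threshold: float,
    n_pcs: int = 3,
    gap_tol_bins: int = 2,
    assignments: Mapping[str, object] | None = None,
) -> RegionSet:
    """Select, merge and annotate regions at one threshold."""
    selected = threshold_loadings(model, threshold, n_pcs)
    regions = merge_bins_to_ranges(selected, bin_edges, gap_tol_bins)
    per_pc = per_pc_selections(model, threshold, n_pcs)
    contributing: list[tuple[int, ...]] = []
    edges = np.asarray(bin_edges, dtype=float)
    for lo, hi in regions:
        inside = (edges[:, 0] >= lo - _EDGE_TOL) & (edges[:, 1] <= hi + _EDGE_TOL)
        pcs = tuple(
            pc for pc, idx in per_pc.items() if idx.size and np.any(inside[idx]))
        contributing.append(pcs)
    annotations = annotate_ranges(regions, assignments)
    return RegionSet(threshold, regions, contributing, annotations)


def run_threshold_ladder(
    model: PCAModel,
    bin_edges: np.ndarray,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    n_pcs: int = 3,
    gap_tol_bins: int = 2,
    assignments: Mapping[str, object] | None = None,
) -> list[RegionSet]:
    """One RegionSet per threshold, in descending threshold order."""
    out = []
    for thr in sorted(thresholds, reverse=True):
        rs = build_region_set(model, bin_edges, thr, n_pcs, gap_tol_bins, assignments)
        out.append(rs)
    return out
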