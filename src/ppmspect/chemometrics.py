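"""Mean-centering, Pareto scaling, and PCA of the binned spectral matrix.

Pareto scaling divides each centered column by the square root of its
standard deviation — intermediate between no scaling and autoscaling, it
damps the dominance of intense peaks while keeping some weighting by
variance, the conventional choice for NMR bin tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import chi2


class ChemometricsError(ValueError):
    pass


#: columns with sample sd below this are centered only (scale recorded as 1)
_SD_FLOOR = 1e-12


def pareto_scale(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-center and Pareto-scale columns: x' = (x − mean) / sqrt(sd).

    sd uses the n−1 denominator. Returns (scaled matrix, means, scales) where
    ``scales[j] = sqrt(sd_j)`` (1 for near-constant columns, which end up
    all-zero rather than NaN).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ChemometricsError("need a 2-D matrix with at least 2 samples")
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scales = np.where(sd > _SD_FLOOR, np.sqrt(np.maximum(sd, _SD_FLOOR)), 1.0)
    return (X - means) / scales, means, scales


def apply_scaling(rows: np.ndarray, means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Apply stored centering/scaling to new raw rows."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != means.size:
        raise ChemometricsError(
            f"row length {rows.shape[1]} does not match {means.size} stored columns")
    return (rows - means) / scales


@dataclass
class PCAModel:
    """PCA of a centered/Pareto-scaled matrix.

    loadings: (bins, k) orthonormal columns; scores: (samples, k);
    explained_variance_ratio: fractions of total variance, non-increasing.
    column_means/column_scale reproduce the scaling for projecting new rows.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    column_means: np.ndarray
    column_scale: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[1])


def fit_pca(
    scaled: np.ndarray,
    k: int,
    column_means: np.ndarray | None = None,
    column_scale: np.ndarray | None = None,
) -> PCAModel:
    """Fit a k-component PCA to an already centered/scaled matrix.

    Loadings are the top-k right singular vectors, with a deterministic sign
    convention: each loading's largest-magnitude entry is made positive.
    """
    X = np.asarray(scaled, dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ChemometricsError(f"k={k} out of range [1, {min(n - 1, p)}]")
    U, s, Vt = linalg.svd(X, full_matrices=False)
    loadings = Vt[:k].T
    # sign convention
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = X @ loadings
    total = float(np.sum(s ** 2))
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    if column_means is None:
        column_means = np.zeros(p)
    if column_scale is None:
        column_scale = np.ones(p)
    return PCAModel(loadings, scores, evr, column_means, column_scale)


def fit_pareto_pca(matrix: np.ndarray, k: int) -> PCAModel:
    """Pareto-scale raw rows, then fit PCA; stores the scaling in the model."""
    scaled, means, scales = pareto_scale(matrix)
    return fit_pca(scaled, k, column_means=means, column_scale=scales)


def project(model: PCAModel, rows: np.ndarray, raw: bool = False) -> np.ndarray:
    """Project rows onto the model's loadings.

    With ``raw=True`` the stored column means/scales are applied first;
    otherwise rows are assumed already centered/scaled.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != model.loadings.shape[0]:
        raise ChemometricsError(
            f"row length {rows.shape[1]} != {model.loadings.shape[0]} model bins")
    if raw:
        rows = apply_scaling(rows, model.column_means, model.column_scale)
    return rows @ model.loadings


def flag_score_outliers(model: PCAModel, n_pcs: int = 3, quantile: float = 0.975
                        ) -> np.ndarray:
    """Flag samples whose Mahalanobis distance over the first *n_pcs* score
    dimensions exceeds the χ²(n_pcs) *quantile*.

    Outliers are reported for inspection, never removed automatically.
    Returns a boolean mask over samples.
    """
    k = min(n_pcs, model.n_components)
    S = model.scores[:, :k]
    centered = S - S.mean(axis=0)
    cov = np.cov(centered, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.pinv(cov), centered)
    return d2 > chi2.ppf(quantile, df=k)
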