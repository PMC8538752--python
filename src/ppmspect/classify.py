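"""Supervised step: LOOCV classification, metrics, PC-count sweep, importance.

Leave-one-out cross-validation (LOOCV) is the resampling scheme of choice for
cohorts this small (49 preterm + 18 term): each sample is predicted by a
model trained on the other n−1. Classifiers are Random Forest (RF), gradient
boosting (GBM) and a radial-kernel support vector machine (SVM), with fixed
default hyperparameters — determinism and comparability, not tuning:

* RF: 500 trees, √p features per split
* GBM: 100 stages, depth 3, learning rate 0.1
* SVM: RBF kernel, C = 1, γ = 1/(p·var)

The positive class is *preterm* throughout. Per-fold model seeds are derived
deterministically from (global seed, fold index), so the prediction for
sample i does not depend on the ordering of the other samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.svm import SVC

from .chemometrics import PCAModel, fit_pareto_pca, fit_pca, pareto_scale, project
from .preprocess import BinnedMatrix

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "preterm"
NEGATIVE_CLASS = "term"
MODEL_ORDER = ("RF", "GBM", "SVM")
DEFAULT_K_RANGE = tuple(range(3, 11))


class ClassifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Confusion rates and derived metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionRates:
    """Per-class confusion rates with the class sizes they were computed on."""

    tpr: float
    tnr: float
    fpr: float
    fnr: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        for name in ("tpr", "tnr", "fpr", "fnr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ClassifyError(f"{name}={v} outside [0, 1]")
        if abs(self.tpr + self.fnr - 1.0) > 0.02 or abs(self.fpr + self.tnr - 1.0) > 0.02:
            raise ClassifyError("rates inconsistent: tpr+fnr and fpr+tnr must be ~1")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ClassifyError("class sizes must be >= 1")


def metrics_from_rates(rates: ConfusionRates) -> tuple[float, float, float]:
    """Accuracy, F1 and precision implied by confusion rates and class sizes.

    accuracy  = (tpr·n_pos + tnr·n_neg) / (n_pos + n_neg)
    precision = tpr·n_pos / (tpr·n_pos + fpr·n_neg)
    f1        = 2·precision·tpr / (precision + tpr)

    With zero predicted positives, precision and F1 are defined as 0 (a
    warning is emitted).
    """
    tp = rates.tpr * rates.n_pos
    fp = rates.fpr * rates.n_neg
    tn = rates.tnr * rates.n_neg
    accuracy = (tp + tn) / (rates.n_pos + rates.n_neg)
    if tp + fp <= 0:
        warnings.warn("no predicted positives; precision and F1 defined as 0")
        return accuracy, 0.0, 0.0
    precision = tp / (tp + fp)
    f1 = 0.0 if precision + rates.tpr == 0 else \
        2 * precision * rates.tpr / (precision + rates.tpr)
    return accuracy, f1, precision


@dataclass(frozen=True)
class MetricsRow:
    """One classifier's LOOCV performance (the shape of a report row)."""

    model_name: str
    accuracy: float
    f1: float
    rates: ConfusionRates
    feature_mode: str = "bins"  # "bins" or "pcs"
    n_pcs: int | None = None

    def to_report_dict(self) -> dict:
        return {
            "model": self.model_name,
            "accuracy": round(self.accuracy, 4),
            "f1": round(self.f1, 4),
            "fpr": round(self.rates.fpr, 4),
            "fnr": round(self.rates.fnr, 4),
            "tpr": round(self.rates.tpr, 4),
            "tnr": round(self.rates.tnr, 4),
            "feature_mode": self.feature_mode,
            "n_pcs": self.n_pcs,
        }


def rates_from_predictions(labels: np.ndarray, predictions: np.ndarray) -> ConfusionRates:
    """Confusion rates of predicted vs true labels (positive = preterm)."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    pos = labels == POSITIVE_CLASS
    neg = ~pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassifyError("both classes must be present in the true labels")
    tpr = float(np.mean(predictions[pos] == POSITIVE_CLASS))
    tnr = float(np.mean(predictions[neg] != POSITIVE_CLASS))
    return ConfusionRates(tpr=tpr, tnr=tnr, fpr=1 - tnr, fnr=1 - tpr,
                          n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# Models and the LOOCV loop
# ---------------------------------------------------------------------------

def _fold_seed(seed: int, fold: int) -> int:
    """Deterministic per-fold model seed below 2^31."""
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2 ** 31))


def make_model(model_name: str, seed: int):
    """Unfitted sklearn classifier with the frozen default hyperparameters."""
    if model_name == "RF":
        return RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed)
    if model_name == "GBM":
        return GradientBoostingClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1, random_state=seed)
    if model_name == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    raise ClassifyError(f"unknown model {model_name!r}; expected one of {MODEL_ORDER}")


ModelFactory = Callable[[int], object]


def loocv(
    features: np.ndarray,
    labels: Sequence[str],
    model: str | ModelFactory,
    seed: int = 0,
    feature_mode: str = "bins",
    n_pcs: int | None = None,
) -> tuple[np.ndarray, ConfusionRates, MetricsRow]:
    """Leave-one-out cross-validation on a fixed feature matrix.

    *model* is either one of {"RF", "GBM", "SVM"} or a callable
    ``factory(fold_seed) -> unfitted estimator`` (used e.g. for oracle
    models in tests). Returns the n held-out predictions, the confusion
    rates, and a metrics row.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < 4:
        raise ClassifyError("LOOCV needs at least 4 samples")
    classes = set(y)
    if not {POSITIVE_CLASS, NEGATIVE_CLASS} <= classes or len(classes) != 2:
        raise ClassifyError(f"labels must be exactly {{preterm, term}}, got {classes}")
    name = model if isinstance(model, str) else getattr(model, "__name__", "custom")
    factory: ModelFactory = (lambda s: make_model(model, s)) if isinstance(model, str) \
        else model

    predictions = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if len(set(y_tr)) < 2:
            raise ClassifyError(f"training fold {i} lost one class entirely")
        est = factory(_fold_seed(seed, i))
        est.fit(X[mask], y_tr)
        predictions[i] = est.predict(X[i:i + 1])[0]
    rates = rates_from_predictions(y, predictions)
    accuracy, f1, _ = metrics_from_rates(rates)
    row = MetricsRow(name, accuracy, f1, rates, feature_mode=feature_mode, n_pcs=n_pcs)
    return predictions, rates, row


# ---------------------------------------------------------------------------
# LOOCV on principal-component scores
# ---------------------------------------------------------------------------

def fold_pc_features(
    matrix: np.ndarray, k_max: int, leakage_mode: str = "strict"
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-fold (train scores, held-out score) pairs with k_max components.

    strict: Pareto scaling and PCA are refit on the n−1 training rows of each
    fold and the held-out row is projected through the training transform —
    the held-out sample never influences the feature space.
    global: scaling and PCA are fit once on all rows (compatibility mode for
    pipelines that fit PCA before cross-validation).

    The top-k columns of a k_max-component PCA equal the k-component PCA, so
    callers can slice ``[:, :k]`` for any k ≤ k_max — fold transforms are
    computed once per cohort, not once per (model, k).
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if leakage_mode == "global":
        model = fit_pareto_pca(X, k_max)
        return [(np.delete(model.scores, i, axis=0), model.scores[i]) for i in range(n)]
    if leakage_mode != "strict":
        raise ClassifyError(f"leakage_mode must be 'strict' or 'global', not {leakage_mode!r}")
    folds = []
    for i in range(n):
        train = np.delete(X, i, axis=0)
        scaled, means, scales = pareto_scale(train)
        model = fit_pca(scaled, k_max, column_means=means, column_scale=scales)
        test_score = project(model, X[i], raw=True)[0]
        folds.append((model.scores, test_score))
    return folds


def loocv_on_pcs(
    binned: BinnedMatrix | np.ndarray,
    labels: Sequence[str],
    model: str | ModelFactory,
    k: int,
    seed: int = 0,
    leakage_mode: str = "strict",
    _folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> MetricsRow:
    """LOOCV with the first *k* principal-component scores as features."""
    X = binned.matrix if isinstance(binned, BinnedMatrix) else np.asarray(binned)
    y = np.asarray(labels)
    n = X.shape[0]
    if not 1 <= k <= n - 2:
        raise ClassifyError(f"k={k} out of range [1, {n - 2}]")
    folds = _folds if _folds is not None else fold_pc_features(X, k, leakage_mode)
    name = model if isinstance(model, str) else getattr(model, "__name__", "custom")
    factory: ModelFactory = (lambda s: make_model(model, s)) if isinstance(model, str) \
        else model
    predictions = np.empty(n, dtype=y.dtype)
    for i, (train_scores, test_score) in enumerate(folds):
        est = factory(_fold_seed(seed, i))
        est.fit(train_scores[:, :k], np.delete(y, i))
        predictions[i] = est.predict(test_score[None, :k])[0]
    rates = rates_from_predictions(y, predictions)
    accuracy, f1, _ = metrics_from_rates(rates)
    return MetricsRow(name, accuracy, f1, rates, feature_mode="pcs", n_pcs=k)


@dataclass
class SweepResult:
    """Accuracy per (model, PC count) and the argmax."""

    accuracies: dict[tuple[str, int], float]
    rows: list[MetricsRow]
    best_model: str
    best_k: int

    @property
    def best_accuracy(self) -> float:
        return self.accuracies[(self.best_model, self.best_k)]


def sweep_pc_count(
    binned: BinnedMatrix | np.ndarray,
    labels: Sequence[str],
    models: Sequence[str] = MODEL_ORDER,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    seed: int = 0,
    leakage_mode: str = "strict",
) -> SweepResult:
    """LOOCV accuracy over a grid of PC counts for each model.

    Ties on accuracy break toward the smaller k, then model order RF < GBM <
    SVM. Fold PC transforms are shared across the whole grid.
    """
    X = binned.matrix if isinstance(binned, BinnedMatrix) else np.asarray(binned)
    y = np.asarray(labels)
    k_range = sorted(k_range)
    if k_range[-1] > X.shape[0] - 2:
        raise ClassifyError(f"max k {k_range[-1]} exceeds n-2 = {X.shape[0] - 2}")
    folds = fold_pc_features(X, k_range[-1], leakage_mode)
    accuracies: dict[tuple[str, int], float] = {}
    rows: list[MetricsRow] = []
    for model in models:
        for k in k_range:
            row = loocv_on_pcs(X, y, model, k, seed=seed,
                               leakage_mode=leakage_mode, _folds=folds)
            accuracies[(model, k)] = row.accuracy
            rows.append(row)
            logger.debug("sweep %s k=%d accuracy=%.3f", model, k, row.accuracy)
    order = {m: i for i, m in enumerate(MODEL_ORDER)}
    best_model, best_k = max(
        accuracies, key=lambda mk: (accuracies[mk], -mk[1], -order.get(mk[0], 99)))
    return SweepResult(accuracies, rows, best_model, best_k)


def rf_pc_importance(
    scores: np.ndarray,
    labels: Sequence[str],
    seed: int = 0,
    n_repeats: int = 50,
    mode: str = "permutation",
) -> tuple[np.ndarray, np.ndarray]:
    """Random-forest importance of each principal component.

    Default is permutation importance: the mean accuracy drop over
    *n_repeats* shuffles of each score column, clipped at 0, with its
    Monte-Carlo standard deviation. ``mode="impurity"`` returns the forest's
    impurity-based importances instead (sd = 0).

    Samples are put in a canonical (lexicographic) order before fitting, so
    the reported importances do not depend on input row order.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    order = np.lexsort(X.T[::-1])
    X, y = X[order], y[order]
    rf = make_model("RF", _fold_seed(seed, 0))
    rf.fit(X, y)
    if mode == "impurity":
        return rf.feature_importances_.copy(), np.zeros(X.shape[1])
    if mode != "permutation":
        raise ClassifyError(f"mode must be 'permutation' or 'impurity', not {mode!r}")
    res = permutation_importance(
        rf, X, y, scoring="accuracy", n_repeats=n_repeats,
        random_state=_fold_seed(seed, 1))
    return np.clip(res.importances_mean, 0.0, None), res.importances_std.copy()


# ---------------------------------------------------------------------------
# Group-summary tests (cohort characteristics tables)
# ---------------------------------------------------------------------------

def compare_groups_summary(
    mean1: float | None = None, sd1: float | None = None, n1: int | None = None,
    mean2: float | None = None, sd2: float | None = None, n2: int | None = None,
    table: Sequence[Sequence[float]] | None = None,
) -> tuple[float, float]:
    """Two-group comparison from summary statistics.

    Continuous summaries → Welch's unpaired t-test from (mean, sd, n) pairs.
    A 2×2 counts *table* → Pearson χ² without continuity correction.
    Returns (statistic, p-value).
    """
    if table is not None:
        tab = np.asarray(table, dtype=float)
        if tab.shape != (2, 2) or np.any(tab < 0):
            raise ClassifyError("table must be a nonnegative 2x2 counts table")
        stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
        return float(stat), float(p)
    if None in (mean1, sd1, n1, mean2, sd2, n2):
        raise ClassifyError("provide either all six summary values or a 2x2 table")
    if n1 < 2 or n2 < 2:
        raise ClassifyError("need n >= 2 per group for the t-test")
    if sd1 == 0 and sd2 == 0:
        raise ClassifyError("zero standard deviation in both groups")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    return float(res.statistic), float(res.pvalue)
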