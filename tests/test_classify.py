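"""LOOCV classification: metric identities, the CV loop, sweep, importance."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from ppmspect import (
    ClassifyError, ConfusionRates, compare_groups_summary, loocv,
    loocv_on_pcs, metrics_from_rates, rates_from_predictions, rf_pc_importance,
    sweep_pc_count,
)
from ppmspect.classify import MODEL_ORDER, fold_pc_features


def _labels(n_pos, n_neg):
    return np.array(["preterm"] * n_pos + ["term"] * n_neg)


class TestMetricsFromRates:
    @pytest.mark.parametrize("tpr, tnr, accuracy, f1", [
        (0.94, 0.06, 0.70, 0.82),  # forest on scaled bins
        (0.88, 0.28, 0.72, 0.82),  # boosting on scaled bins
        (1.00, 0.00, 0.73, 0.84),  # SVM: predicts every sample preterm
    ])
    def test_rate_identities_for_49_vs_18(self, tpr, tnr, accuracy, f1):
        """With class sizes 49/18, accuracy and F1 follow from the four
        confusion rates by closed-form identities (2-decimal rounding)."""
        rates = ConfusionRates(tpr=tpr, tnr=tnr, fpr=1 - tnr, fnr=1 - tpr,
                               n_pos=49, n_neg=18)
        acc, f1_, _ = metrics_from_rates(rates)
        assert round(acc, 2) == accuracy
        assert round(f1_, 2) == f1

    def test_perfect_classifier(self):
        rates = ConfusionRates(1.0, 1.0, 0.0, 0.0, n_pos=10, n_neg=5)
        acc, f1, precision = metrics_from_rates(rates)
        assert (acc, f1, precision) == (1.0, 1.0, 1.0)

    def test_no_predicted_positives_gives_zero_f1_with_warning(self):
        rates = ConfusionRates(0.0, 1.0, 0.0, 1.0, n_pos=4, n_neg=4)
        with pytest.warns(UserWarning, match="no predicted positives"):
            acc, f1, precision = metrics_from_rates(rates)
        assert f1 == 0.0 and precision == 0.0 and acc == 0.5

    def test_inconsistent_rates_rejected(self):
        with pytest.raises(ClassifyError):
            ConfusionRates(0.9, 0.9, 0.5, 0.1, n_pos=5, n_neg=5)


class TestLoocvLoop:
    def test_enumeration_oracle_with_1nn(self):
        """The LOOCV loop reproduces an exhaustive hand enumeration of all 6
        folds with a 1-nearest-neighbour stand-in model."""
        X = np.array([[0.0], [1.0], [5.0], [6.0], [10.0], [11.0]])
        y = np.array(["preterm", "preterm", "term", "preterm", "term", "term"])

        expected = np.empty(6, dtype=y.dtype)
        for i in range(6):  # independent brute-force enumeration
            others = [j for j in range(6) if j != i]
            nearest = min(others, key=lambda j: abs(X[j, 0] - X[i, 0]))
            expected[i] = y[nearest]

        preds, _, _ = loocv(X, y, lambda s: KNeighborsClassifier(n_neighbors=1))
        np.testing.assert_array_equal(preds, expected)

    def test_separable_clusters_classified_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(3, 0.1, (8, 3))])
        _, rates, row = loocv(X, _labels(10, 8), "SVM", seed=0)
        assert row.accuracy == 1.0
        assert rates.tpr == 1.0 and rates.tnr == 1.0

    def test_prediction_invariant_to_other_sample_order(self, rng):
        """Sample i's held-out prediction does not depend on how the other
        samples are ordered (per-fold seeds are index-keyed)."""
        X = rng.standard_normal((10, 3))
        y = _labels(6, 4)
        preds, _, _ = loocv(X, y, "SVM", seed=3)
        perm = np.r_[0, 1 + np.argsort(rng.random(9))]  # keep sample 0 first
        preds_p, _, _ = loocv(X[perm], y[perm], "SVM", seed=3)
        assert preds[0] == preds_p[0]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ClassifyError):
            loocv(np.ones((3, 2)), _labels(2, 1), "SVM")

    def test_unknown_model_rejected(self, rng):
        with pytest.raises(ClassifyError, match="unknown model"):
            loocv(rng.random((6, 2)), _labels(3, 3), "QDA")


class TestLoocvOnPcs:
    def test_k_bounds(self, rng):
        X = rng.standard_normal((10, 12))
        y = _labels(6, 4)
        loocv_on_pcs(X, y, "SVM", k=8)        # k = n-2 accepted
        with pytest.raises(ClassifyError):
            loocv_on_pcs(X, y, "SVM", k=9)    # k = n-1 rejected

    def test_strict_and_global_agree_at_large_n(self, rng):
        """With n ≫ bins and a strong planted signal, refitting the PCA
        inside each fold changes LOOCV accuracy by at most 0.02."""
        n = 250
        y = _labels(n // 2, n // 2)
        signal = (y == "preterm").astype(float)[:, None]
        X = 0.8 * signal * rng.random(30) + rng.standard_normal((n, 30)) * 0.4
        strict = loocv_on_pcs(X, y, "SVM", k=3, seed=0, leakage_mode="strict")
        global_ = loocv_on_pcs(X, y, "SVM", k=3, seed=0, leakage_mode="global")
        assert abs(strict.accuracy - global_.accuracy) <= 0.02

    def test_strict_fold_features_exclude_held_out_sample(self, rng):
        """Moving the held-out row must not change its fold's training PCA."""
        X = rng.standard_normal((8, 5))
        folds_a = fold_pc_features(X, 2, "strict")
        X2 = X.copy()
        X2[3] += 100.0
        folds_b = fold_pc_features(X2, 2, "strict")
        np.testing.assert_allclose(folds_a[3][0], folds_b[3][0])

    def test_bad_leakage_mode_rejected(self, rng):
        with pytest.raises(ClassifyError):
            fold_pc_features(rng.random((6, 3)), 2, "weak")


class TestSweep:
    def test_grid_cardinality_and_degenerate_features(self):
        """On all-identical features every (model, k) cell predicts the
        training-fold majority, so each accuracy equals the majority rate."""
        X = np.full((12, 12), 2.0)
        y = _labels(7, 5)
        sw = sweep_pc_count(X, y, models=MODEL_ORDER, seed=0)
        assert len(sw.accuracies) == len(MODEL_ORDER) * 8  # k in 3..10
        majority_rate = 7 / 12
        for acc in sw.accuracies.values():
            assert acc == pytest.approx(majority_rate)

    def test_tie_breaks_prefer_small_k_then_model_order(self):
        X = np.full((12, 12), 1.0)
        sw = sweep_pc_count(X, _labels(7, 5), models=("SVM", "GBM"), seed=0)
        assert sw.best_model == "GBM"  # all tied → GBM before SVM
        assert sw.best_k == 3

    def test_k_above_n_minus_2_rejected(self, rng):
        with pytest.raises(ClassifyError):
            sweep_pc_count(rng.random((9, 12)), _labels(5, 4), seed=0)


class TestRfImportance:
    def test_planted_signal_pc_ranks_first(self, rng):
        """A PC carrying a separable group signal outranks pure-noise PCs in
        at least 90% of 10 seeds."""
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = _labels(15, 15)
            scores = r.standard_normal((30, 3))
            scores[:, 1] += 3.0 * (y == "preterm")
            imp, _ = rf_pc_importance(scores, y, seed=seed, n_repeats=10)
            wins += int(np.argmax(imp)) == 1
        assert wins >= 9

    def test_noise_pc_importance_is_null(self, rng):
        y = _labels(20, 20)
        scores = rng.standard_normal((40, 3))
        scores[:, 0] += 3.0 * (y == "preterm")
        imp, sd = rf_pc_importance(scores, y, seed=0)
        for j in (1, 2):  # label-independent PCs
            assert imp[j] <= max(2 * sd[j], 0.05)

    def test_invariant_to_sample_order(self, rng):
        y = _labels(15, 10)
        scores = rng.standard_normal((25, 3))
        imp_a, _ = rf_pc_importance(scores, y, seed=4, n_repeats=10)
        perm = rng.permutation(25)
        imp_b, _ = rf_pc_importance(scores[perm], y[perm], seed=4, n_repeats=10)
        np.testing.assert_array_equal(imp_a, imp_b)


class TestGroupSummaries:
    def test_gestational_age_separates_groups(self):
        """Welch's t on the cohort's gestational-age summaries is highly
        significant (30.25±2.72 wk, n=49 vs 38.52±1.44 wk, n=18)."""
        t, p = compare_groups_summary(30.25, 2.72, 49, 38.52, 1.44, 18)
        assert p < 0.05
        assert t < 0

    def test_identical_summaries_are_null(self):
        t, p = compare_groups_summary(5.0, 1.0, 20, 5.0, 1.0, 20)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_sex_ratio_not_significant(self):
        """Male fraction 31/49 vs 12/18: Pearson χ² (no continuity
        correction), checked against the hand-computed statistic."""
        table = [[31, 49 - 31], [12, 18 - 12]]
        stat, p = compare_groups_summary(table=table)
        # independent hand computation of Pearson chi-square
        obs = np.array(table, dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        by_hand = float(((obs - exp) ** 2 / exp).sum())
        assert stat == pytest.approx(by_hand, rel=1e-12)
        assert p > 0.05

    def test_zero_spread_rejected(self):
        with pytest.raises(ClassifyError):
            compare_groups_summary(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_bad_table_rejected(self):
        with pytest.raises(ClassifyError):
            compare_groups_summary(table=[[1, 2, 3], [4, 5, 6]])
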