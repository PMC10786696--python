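"""Constrained logistic regression, Shapley attribution, CV machinery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from cfmethyl import (
    CohortSpec,
    build_feature_matrix,
    confusion_metrics,
    feature_sweep,
    fit_constrained_logistic,
    generate_cohort,
    rank_by_shapley,
    rank_features,
    repeated_kfold,
    roc_auc,
    shapley_exact,
    shapley_values,
)
from cfmethyl.model import ConstrainedLRFit
from cfmethyl.synthetic import FEATURES_17


def simulate_logistic(beta, n, seed, intercept=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    p = 1 / (1 + np.exp(-(intercept + X @ np.asarray(beta))))
    return X, (rng.random(n) < p).astype(int)


class TestBuildFeatureMatrix:
    def test_filters_and_labels(self):
        tab = generate_cohort(CohortSpec(seed=0))
        X, y = build_feature_matrix(tab)
        assert list(X.columns) == list(FEATURES_17)
        assert not X.isna().any().any()  # complete cases only
        assert set(np.unique(y)) == {0, 1}
        hct = tab[tab.group != "healthy"]
        assert len(X) == len(hct.dropna(subset=list(FEATURES_17)))


class TestConstrainedFit:
    def test_negatively_associated_feature_clamped_to_zero(self):
        X, y = simulate_logistic([-2.0, 1.0], 500, seed=1)
        fit = fit_constrained_logistic(X, y, nonneg=True)
        assert fit.coef[0] == 0.0  # exactly zero at the active bound
        assert fit.coef[1] > 0

    def test_parameter_recovery_and_unconstrained_agreement(self):
        """Nonnegative truth beta=(1,2) at n=2000: constrained fit recovers
        it within +-0.15 and agrees with the unconstrained MLE (sklearn,
        penalty-free) since the constraint is inactive."""
        X, y = simulate_logistic([1.0, 2.0], 2000, seed=2)
        fit = fit_constrained_logistic(X, y, nonneg=True)
        assert fit.coef == pytest.approx([1.0, 2.0], abs=0.15)
        mle = LogisticRegression(C=np.inf, max_iter=1000).fit(X, y)
        assert fit.coef == pytest.approx(mle.coef_[0], abs=0.02)
        assert fit.intercept == pytest.approx(mle.intercept_[0], abs=0.02)

    def test_null_coefficients_center_on_zero(self):
        """Labels independent of features: unconstrained coefficients average
        to ~0 over seeds."""
        coefs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 2))
            y = rng.integers(0, 2, size=500)
            coefs.append(fit_constrained_logistic(X, y, nonneg=False).coef)
        assert np.abs(np.mean(coefs, axis=0)).max() < 0.05

    def test_separation_is_flagged_and_finite(self):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        fit = fit_constrained_logistic(X, y)
        assert np.isfinite(fit.coef).all()
        assert fit.separation_flag

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_constrained_logistic(np.zeros((10, 2)), np.ones(10))

    def test_missing_rejected(self):
        X = np.zeros((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_constrained_logistic(X, np.tile([0, 1], 5))


class TestShapley:
    def test_zero_weight_feature_gets_zero_attribution(self):
        fit = ConstrainedLRFit(["a", "b"], 0.0, np.array([1.0, 0.0]), True, 0.0, True)
        rep = shapley_values(fit, np.array([[2.0, 9.0]]), np.array([[1.0, 5.0]]))
        assert rep.values.iloc[0].tolist() == pytest.approx([1.0, 0.0])

    def test_efficiency_identity(self):
        rng = np.random.default_rng(0)
        fit = ConstrainedLRFit(
            [f"f{i}" for i in range(4)], 0.3, rng.uniform(0, 2, 4), True, 0.0, True
        )
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=fit.feature_names)
        bg = pd.DataFrame(rng.normal(size=(30, 4)), columns=fit.feature_names)
        rep = shapley_values(fit, X, bg)
        total = rep.values.sum(axis=1).to_numpy()
        expected = fit.decision_function(X) - rep.base_log_odds
        assert total == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("p", [2, 5])
    def test_closed_form_equals_exhaustive_enumeration(self, p):
        rng = np.random.default_rng(p)
        fit = ConstrainedLRFit(
            [f"f{i}" for i in range(p)], 0.5, rng.uniform(0, 2, p), True, 0.0, True
        )
        bg = rng.normal(size=(40, p))
        x = rng.normal(size=p)
        rep = shapley_values(fit, x.reshape(1, -1), bg)
        oracle = shapley_exact(fit, x, bg.mean(axis=0))
        assert rep.values.iloc[0].to_numpy() == pytest.approx(oracle, abs=1e-9)

    def test_empty_background_rejected(self):
        fit = ConstrainedLRFit(["a"], 0.0, np.array([1.0]), True, 0.0, True)
        with pytest.raises(ValueError):
            shapley_values(fit, np.array([[1.0]]), np.empty((0, 1)))


class TestRankFeatures:
    def _report(self, mean_abs):
        class R:
            pass

        r = R()
        r.mean_abs = pd.Series(mean_abs)
        return r

    def test_descending_order(self):
        ranking, ties = rank_features(self._report({"A": 0.5, "B": 0.2, "C": 0.0}))
        assert ranking == ["A", "B", "C"]
        assert not ties

    def test_tie_breaks_lexicographic_and_flagged(self):
        ranking, ties = rank_features(self._report({"zeta": 0.3, "alpha": 0.3, "mid": 0.9}))
        assert ranking == ["mid", "alpha", "zeta"]
        assert ties

    def test_planted_signal_features_rank_top(self):
        """The three calibrated signal features occupy the top Shapley ranks
        in the large majority of cohort draws."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            tab = generate_cohort(CohortSpec(seed=seed))
            X, y = build_feature_matrix(tab)
            ranking, _, _ = rank_by_shapley(X, y)
            hits += set(ranking[:3]) == {"alt", "cfdna_total_ng_ml", "cf_monocyte"}
        assert hits >= 0.8 * n_seeds


class TestConfusionMetrics:
    def test_hand_computed_table(self):
        """TP=8, FN=2, TN=9, FP=1."""
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 8 + [0] * 2 + [0] * 9 + [1]
        m = confusion_metrics(y_true, y_pred)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["ppv"] == pytest.approx(8 / 9)
        assert m["npv"] == pytest.approx(9 / 11)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["precision"] == m["ppv"] and m["recall"] == m["sensitivity"]

    def test_perfect_predictions(self):
        m = confusion_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert all(v == 1.0 for v in m.values())

    def test_no_positive_predictions_ppv_undefined(self):
        m = confusion_metrics([0, 1], [0, 0])
        assert np.isnan(m["ppv"])
        assert m["specificity"] == 1.0 and m["sensitivity"] == 0.0


class TestRocAuc:
    def test_pair_counting_example(self):
        """3 of 4 positive-negative pairs concordant -> AUC 0.75."""
        res = roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_and_tied(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]).auc == 1.0
        assert roc_auc([0, 1, 0, 1], [0.5] * 4).auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        s = np.round(rng.random(60), 2)  # induce ties
        pos, neg = s[y == 1], s[y == 0]
        pairs = (pos[:, None] > neg[None, :]).mean() + 0.5 * (
            pos[:, None] == neg[None, :]
        ).mean()
        assert roc_auc(y, s).auc == pytest.approx(pairs, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        base = roc_auc(y, s).auc
        assert roc_auc(y, np.exp(s)).auc == pytest.approx(base)
        assert roc_auc(y, 3 * s - 7).auc == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


@pytest.fixture(scope="module")
def cohort_Xy():
    tab = generate_cohort(CohortSpec(seed=4))
    return build_feature_matrix(tab)


class TestRepeatedKFold:
    def test_partition_validity(self, cohort_Xy):
        """Every sample is tested exactly once per repeat."""
        X, y = cohort_Xy
        rep = repeated_kfold(X, y, repeats=3, seed=0)
        per_repeat = rep.oof.groupby("repeat")["index"].apply(list)
        for idx in per_repeat:
            assert sorted(idx) == list(range(len(X)))

    def test_seeded_determinism(self, cohort_Xy):
        X, y = cohort_Xy
        a = repeated_kfold(X, y, repeats=2, seed=3)
        b = repeated_kfold(X, y, repeats=2, seed=3)
        pd.testing.assert_frame_equal(a.folds, b.folds)

    def test_perfectly_separable_data_scores_one(self):
        rng = np.random.default_rng(0)
        n = 60
        X = pd.DataFrame({"f": np.r_[rng.uniform(0, 1, n // 2), rng.uniform(9, 10, n // 2)]})
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        rep = repeated_kfold(X, y, repeats=2, seed=1)
        assert rep.summary.loc["auc", "mean"] == pytest.approx(1.0)
        assert rep.summary.loc["accuracy", "mean"] == pytest.approx(1.0)

    def test_permuted_labels_auc_near_half(self, cohort_Xy):
        X, y = cohort_Xy
        rng = np.random.default_rng(7)
        yp = rng.permutation(y)
        rep = repeated_kfold(X, yp, feature_set=list(X.columns[:5]), repeats=20, seed=2)
        assert 0.4 <= rep.summary.loc["auc", "mean"] <= 0.6

    def test_metrics_within_unit_interval(self, cohort_Xy):
        X, y = cohort_Xy
        rep = repeated_kfold(X, y, repeats=2, seed=5)
        vals = rep.folds[["accuracy", "sensitivity", "specificity", "auc"]].to_numpy()
        vals = vals[~np.isnan(vals)]
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_bad_k_rejected(self, cohort_Xy):
        X, y = cohort_Xy
        with pytest.raises(ValueError):
            repeated_kfold(X, y, k=1)


class TestFeatureSweep:
    def test_single_informative_feature_plateaus_after_one(self):
        rng = np.random.default_rng(0)
        n = 200
        y = rng.integers(0, 2, size=n)
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        X["a"] += 3.0 * y  # only 'a' carries signal
        sw = feature_sweep(X, y, ["a", "b", "c", "d"], repeats=3, seed=0)
        aucs = sw.table["auc_mean"]
        assert aucs[1] > 0.95
        assert (aucs[2:] - aucs[1]).abs().max() < 0.05

    def test_default_sizes_one_to_seven(self):
        tab = generate_cohort(CohortSpec(seed=6))
        X, y = build_feature_matrix(tab)
        sw = feature_sweep(X, y, list(FEATURES_17), repeats=2, seed=0)
        assert list(sw.table.index) == [1, 2, 3, 4, 5, 6, 7]
        assert sw.best_features == sw.ranking[: sw.best_size]
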