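"""AUROC estimator, confusion metrics, bootstrap test, CV and calibration."""

import numpy as np
import pandas as pd
import pytest

from fastlabel.model_eval import (
    MetricsReport,
    ModelConfig,
    bootstrap_auroc_difference,
    calibration,
    compute_auroc,
    confusion_metrics,
    crossvalidate,
    fit_model,
)


def _pair_oracle(scores, labels):
    """Exhaustive positive-negative pair enumeration (ties count one half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


class TestAuroc:
    def test_perfect_separation(self):
        assert compute_auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_brute_force_three_quarters(self):
        assert compute_auroc([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert compute_auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            compute_auroc([0.1, 0.9], [1, 1])

    def test_equals_pair_oracle_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(4, 120)
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            s = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], n)
            assert compute_auroc(s, y) == pytest.approx(_pair_oracle(s, y))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        s = rng.random(200)
        y = rng.random(200) < 0.5
        assert compute_auroc(np.exp(5 * s), y) == pytest.approx(compute_auroc(s, y))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        s = rng.choice([0.2, 0.5, 0.8], 300)
        y = rng.random(300) < 0.5
        assert compute_auroc(s, y) == pytest.approx(roc_auc_score(y, s))


class TestConfusionMetrics:
    def test_hand_counted_example(self):
        # TP=3, FP=1, FN=1, TN=5
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        s = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.2, 0.3, 0.4]
        rep = confusion_metrics(s, y, threshold=0.5)
        assert rep.sensitivity == 0.75
        assert rep.precision == 0.75
        assert rep.f1 == pytest.approx(0.75)
        assert rep.accuracy == 0.8
        assert rep.specificity == pytest.approx(5 / 6)

    def test_perfect_predictions(self):
        rep = confusion_metrics([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0])
        assert (rep.sensitivity, rep.specificity, rep.precision, rep.f1,
                rep.accuracy, rep.auroc) == (1, 1, 1, 1, 1, 1)

    def test_empty_predicted_positive_set(self):
        rep = confusion_metrics([0.1, 0.2, 0.3, 0.4], [1, 0, 1, 0])
        assert rep.precision is None and rep.f1 is None
        assert rep.sensitivity == 0.0


class TestFitModel:
    def _simulated(self, n, seed=0, beta=(0.5, -1.0), intercept=-0.2):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        logit = intercept + beta[0] * x1 + beta[1] * x2
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        return pd.DataFrame(
            {"glucose_per5": x1, "age_per5": x2,
             "label_nonfasting": pd.array(y, dtype="boolean")}
        )

    def test_logistic_parameter_recovery(self):
        df = self._simulated(20_000, seed=5)
        model = fit_model(df, ModelConfig("logistic"),
                          feature_cols=["glucose_per5", "age_per5"])
        coef = model.coefficients()
        se = model.standard_errors()
        for name, true in (("const", -0.2), ("glucose_per5", 0.5),
                           ("age_per5", -1.0)):
            assert abs(coef[name] - true) <= 3 * se[name]

    def test_intercept_only_predicts_base_rate(self):
        rng = np.random.default_rng(1)
        y = rng.permutation([True] * 300 + [False] * 700)
        df = pd.DataFrame({"label_nonfasting": pd.array(y, dtype="boolean")})
        model = fit_model(df, ModelConfig("logistic"), feature_cols=[])
        p = model.predict_proba(df)
        np.testing.assert_allclose(p, 0.3, atol=1e-6)

    def test_constant_label_raises(self):
        df = self._simulated(100)
        df["label_nonfasting"] = True
        with pytest.raises(ValueError):
            fit_model(df, ModelConfig("logistic"))

    def test_perfect_separation_warns(self):
        x = np.concatenate([np.full(50, -2.0), np.full(50, 2.0)])
        df = pd.DataFrame(
            {"glucose_per5": x,
             "label_nonfasting": pd.array(x > 0, dtype="boolean")}
        )
        with pytest.warns((RuntimeWarning, UserWarning)):
            fit_model(df, ModelConfig("logistic"), feature_cols=["glucose_per5"])

    def test_gbt_scores_are_probabilities(self):
        df = self._simulated(2_000, seed=9)
        model = fit_model(df, ModelConfig("gbt", seed=1),
                          feature_cols=["glucose_per5", "age_per5"])
        p = model.predict_proba(df)
        assert np.all((p >= 0) & (p <= 1))
        assert compute_auroc(p, df["label_nonfasting"].to_numpy(dtype=bool)) > 0.6

    def test_odds_ratio_export_shape(self):
        df = self._simulated(5_000, seed=2)
        model = fit_model(df, ModelConfig("logistic"),
                          feature_cols=["glucose_per5", "age_per5"])
        ors = model.odds_ratios()
        assert {"OR", "ci_lower", "ci_upper", "p_value"} <= set(ors.columns)
        assert (ors["ci_lower"] <= ors["OR"]).all()
        assert (ors["OR"] <= ors["ci_upper"]).all()


class TestBootstrapDifference:
    def test_identical_scorers(self):
        rng = np.random.default_rng(0)
        s = rng.random(200)
        y = rng.random(200) < 0.5
        out = bootstrap_auroc_difference(s, s, y, reps=200, seed=1)
        assert out["delta_auroc"] == 0.0
        assert out["p_value"] > 0.9

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(150), rng.random(150)
        y = rng.random(150) < 0.5
        o1 = bootstrap_auroc_difference(a, b, y, reps=200, seed=5)
        o2 = bootstrap_auroc_difference(a, b, y, reps=200, seed=5)
        assert o1 == o2

    def test_small_reps_warn(self):
        rng = np.random.default_rng(3)
        s = rng.random(60)
        y = rng.random(60) < 0.5
        with pytest.warns(UserWarning):
            bootstrap_auroc_difference(s, s, y, reps=50, seed=0)

    def test_ci_covers_true_difference_on_simulated_data(self):
        rng = np.random.default_rng(11)
        n = 3000
        z = rng.normal(size=n)
        y = rng.random(n) < 1 / (1 + np.exp(-1.5 * z))
        good = 1 / (1 + np.exp(-1.5 * z))
        noisy = 1 / (1 + np.exp(-(1.5 * z + rng.normal(0, 2.0, n))))
        true_delta = compute_auroc(good, y) - compute_auroc(noisy, y)
        out = bootstrap_auroc_difference(good, noisy, y, reps=400, seed=7)
        assert out["ci_lower"] <= true_delta <= out["ci_upper"]
        assert out["p_value"] < 0.05


class TestCrossValidation:
    def test_fold_structure_and_pooling(self):
        df = TestFitModel()._simulated(600, seed=8)
        reports, pooled = crossvalidate(
            df, ModelConfig("logistic"), k=5, seed=0,
            feature_cols=["glucose_per5", "age_per5"],
        )
        assert len(reports) == 5
        sizes = [r.n_pos + r.n_neg for r in reports]
        assert sum(sizes) == 600
        assert max(sizes) - min(sizes) <= 1
        assert isinstance(pooled, MetricsReport)
        assert 0.5 < pooled.auroc <= 1.0

    def test_too_small_input_raises(self):
        df = TestFitModel()._simulated(20)
        with pytest.raises(ValueError):
            crossvalidate(df, k=5, feature_cols=["glucose_per5", "age_per5"])


class TestCalibration:
    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        s = rng.random(500)
        y = rng.random(500) < s
        tab = calibration(s, y)
        assert tab["count"].sum() == 500

    def test_constant_half_scores(self):
        y = [True, False] * 50
        tab = calibration([0.5] * 100, y)
        occupied = tab[tab["count"] > 0]
        assert len(occupied) == 1
        assert occupied["observed_fraction"].iloc[0] == 0.5

    def test_well_calibrated_scores_match_observed(self):
        rng = np.random.default_rng(4)
        s = rng.random(40_000)
        y = rng.random(40_000) < s
        tab = calibration(s, y)
        gap = (tab["mean_predicted"] - tab["observed_fraction"]).abs()
        assert gap.max() < 0.03

    def test_rejects_out_of_range_scores(self):
        with pytest.raises(ValueError):
            calibration([1.2], [True])
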