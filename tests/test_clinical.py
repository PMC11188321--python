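"""Clinical modelling layer: Youden oracle equivalence, logistic ORs,
model set, calibration, DCA identities, nomogram consistency, chi-square."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from petrad import (
    build_models,
    calibration_bootstrap,
    chisq_from_table,
    cohort_chisq,
    dca,
    multivariate_logistic,
    nomogram_points,
    screen_univariate,
    univariate_logistic,
    youden_cutoff,
)
from petrad.clinical import MODEL_VARIABLES, delong_auc_ci


class TestYouden:
    def test_perfect_separation_midpoint_convention(self):
        res = youden_cutoff([1, 2, 8, 9], [0, 0, 1, 1])
        assert res.youden_j == pytest.approx(1.0)
        assert res.threshold == pytest.approx(5.0)
        assert res.auc == pytest.approx(1.0)
        assert res.sensitivity + res.specificity - 1 == pytest.approx(res.youden_j)

    def test_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=200) + np.repeat([0.0, 1.0], 100)
        labels = np.repeat([0, 1], 100)
        res = youden_cutoff(scores, labels)
        # oracle: J at every candidate threshold, including the data points
        best_j = -np.inf
        for t in np.unique(scores):
            pred = scores >= t
            j = (pred & (labels == 1)).sum() / 100 + (~pred & (labels == 0)).sum() / 100 - 1
            best_j = max(best_j, j)
        assert res.youden_j == pytest.approx(best_j, abs=1e-12)

    def test_null_scores_near_zero_j(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=2000)
        labels = (rng.random(2000) < 0.5).astype(int)
        res = youden_cutoff(scores, labels)
        assert abs(res.auc - 0.5) < 0.05
        assert res.youden_j < 0.15

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            youden_cutoff([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])

    def test_delong_ci_brackets_auc(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100) + np.repeat([0, 1], 50)
        auc, lo, hi = delong_auc_ci(scores, np.repeat([0, 1], 50))
        assert lo < auc < hi


class TestLogistic:
    def test_binary_or_equals_cross_product_ratio(self):
        # 2x2 cells (a,b,c,d)=(20,30,10,40): OR = ad/bc = 8/3
        df = pd.DataFrame({
            "x": [1] * 50 + [0] * 50,
            "outcome": [1] * 20 + [0] * 30 + [1] * 10 + [0] * 40,
        })
        res = univariate_logistic(df, "x")
        assert res.odds_ratio("x") == pytest.approx(8 / 3, rel=1e-6)
        lo, hi = res.table.loc["x", ["ci_low", "ci_high"]]
        assert lo < 8 / 3 < hi

    def test_null_coefficient_ci_coverage(self):
        # predictor with zero true effect: 95% Wald CI covers OR=1 in most seeds
        covered = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({
                "x": rng.standard_normal(2000),
                "outcome": (rng.random(2000) < 0.4).astype(int),
            })
            t = univariate_logistic(df, "x").table
            covered += t.loc["x", "ci_low"] <= 1.0 <= t.loc["x", "ci_high"]
        assert covered >= 8

    def test_perfect_separation_raises(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "outcome": np.r_[np.zeros(20), np.ones(20)].astype(int)})
        with pytest.raises(ValueError, match="separation"):
            univariate_logistic(df, "x")

    def test_screening_keeps_only_significant(self):
        rng = np.random.default_rng(3)
        n = 600
        strong = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        y = (rng.random(n) < expit(1.5 * strong)).astype(int)
        df = pd.DataFrame({"strong": strong, "noise": noise, "outcome": y})
        kept = screen_univariate(df, ["strong", "noise"])
        assert "strong" in kept


class TestModelSet:
    @pytest.fixture()
    def scored_cohort(self):
        rng = np.random.default_rng(4)
        n = 600
        df = pd.DataFrame({
            "sex": (rng.random(n) < 0.7).astype(int),
            "b_symptoms": (rng.random(n) < 0.33).astype(int),
            "suvmax_high": (rng.random(n) < 0.45).astype(int),
            "nccn_ipi_68": (rng.random(n) < 0.14).astype(int),
            "ipi_ge3": (rng.random(n) < 0.2).astype(int),
        })
        radscore = rng.standard_normal(n)
        df["radscore_high"] = (radscore > 0).astype(int)
        lp = -1.0 + 2.0 * df["radscore_high"] + 0.4 * df["sex"] + 0.5 * df["b_symptoms"]
        df["outcome"] = (rng.random(n) < expit(lp)).astype(int)
        return df

    def test_combined_model_uses_four_predictors(self, scored_cohort):
        models = build_models(scored_cohort)
        assert models["combined"].result.variables == [
            "sex", "b_symptoms", "suvmax_high", "radscore_high"
        ]
        assert set(models) == set(MODEL_VARIABLES)

    def test_radscore_dominated_data_orders_aucs(self, scored_cohort):
        models = build_models(scored_cohort)
        assert models["combined"].auc_train >= models["clinical"].auc_train

    def test_refit_identical(self, scored_cohort):
        m1 = build_models(scored_cohort)["combined"].result
        m2 = build_models(scored_cohort)["combined"].result
        pd.testing.assert_series_equal(m1.params, m2.params)


class TestCalibration:
    def test_self_consistent_model_slope_near_one(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.standard_normal(n)
        p = expit(-0.5 + 1.2 * x)
        y = (rng.random(n) < p).astype(int)
        df = pd.DataFrame({"x": x, "outcome": y})
        res = multivariate_logistic(df, ["x"])
        calib = calibration_bootstrap(res.predict(df), y, reps=200, seed=5)
        assert 0.9 <= calib["slope"] <= 1.1

    def test_single_rep_is_apparent_curve(self):
        pred = np.linspace(0.05, 0.95, 100)
        obs = (pred > 0.5).astype(int)
        c = calibration_bootstrap(pred, obs, reps=1)
        assert c["reps"] == 1
        assert len(c["curve"]) == 10
        assert ((c["curve"]["predicted"] >= 0) & (c["curve"]["predicted"] <= 1)).all()


class TestDCA:
    def test_perfect_predictor_net_benefit_is_prevalence(self):
        y = np.r_[np.ones(30, int), np.zeros(70, int)]
        pred = y.astype(float)
        curve = dca(pred, y, thresholds=np.arange(0.05, 0.95, 0.05))
        np.testing.assert_allclose(curve["net_benefit"], 0.3, atol=1e-12)

    def test_treat_all_crosses_zero_at_prevalence(self):
        y = np.r_[np.ones(40, int), np.zeros(60, int)]
        pred = np.random.default_rng(0).random(100)
        curve = dca(pred, y, thresholds=np.array([0.4]))
        assert curve["treat_all"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert (dca(pred, y)["treat_none"] == 0).all()

    def test_random_predictor_bounded_by_references(self):
        rng = np.random.default_rng(6)
        n = 2000
        y = (rng.random(n) < 0.3).astype(int)
        pred = rng.random(n)
        curve = dca(pred, y)
        prevalence = y.mean()
        assert (curve["net_benefit"] <= prevalence + 1e-12).all()
        # 2 SE slack around the treat-all/none envelope for a useless model
        se = 2 * np.sqrt(prevalence * (1 - prevalence) / n)
        envelope = np.maximum(curve["treat_all"], 0.0)
        assert (curve["net_benefit"] <= envelope + 2 * se).all()


class TestNomogram:
    def _fit(self, betas, n=400, seed=7):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({f"x{i}": rng.standard_normal(n) for i in range(len(betas))})
        lp = sum(b * X[f"x{i}"] for i, b in enumerate(betas))
        X["outcome"] = (rng.random(n) < expit(lp)).astype(int)
        return multivariate_logistic(X, [f"x{i}" for i in range(len(betas))]), X

    def test_single_predictor_spans_0_to_100(self):
        res, X = self._fit([1.5])
        nomo = nomogram_points(res, X)
        pts = nomo["per_variable"]["x0"]["points"]
        assert pts.min() == pytest.approx(0.0)
        assert pts.max() == pytest.approx(100.0)

    def test_point_allocation_scale_free(self):
        res, X = self._fit([1.0, 0.5])
        nomo1 = nomogram_points(res, X)
        doubled = res
        doubled.params = res.params * 2.0
        nomo2 = nomogram_points(doubled, X)
        for v in ("x0", "x1"):
            np.testing.assert_allclose(
                nomo1["per_variable"][v]["points"], nomo2["per_variable"][v]["points"]
            )

    def test_risk_map_matches_model_probability(self):
        res, X = self._fit([1.0, -0.7], n=300, seed=8)
        nomo = nomogram_points(res, X)
        probs = res.predict(X)
        for i in range(0, 300, 15):  # 20 records
            total = nomo["points_for"](X.iloc[i])
            assert nomo["risk_at_total"](total) == pytest.approx(probs[i], abs=1e-6)


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,expected_p",
        [
            ([[29, 94], [19, 35]], 0.110),    # sex
            ([[102, 21], [40, 14]], 0.173),   # LDH
            ([[86, 37], [33, 21]], 0.250),    # B symptoms
            ([[77, 46], [33, 21]], 0.851),    # bulky disease
            ([[54, 69], [24, 30]], 0.947),    # RadScore group
        ],
    )
    def test_printed_contingency_p_values(self, table, expected_p):
        _, p = chisq_from_table(table)
        assert p == pytest.approx(expected_p, abs=5e-4)

    def test_identical_proportions_give_p_one(self):
        chi2, p = chisq_from_table([[30, 60], [10, 20]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_cohort_interface_matches_table(self):
        train = pd.DataFrame({"sex": [1] * 94 + [0] * 29})
        val = pd.DataFrame({"sex": [1] * 35 + [0] * 19})
        _, p = cohort_chisq(train, val, "sex")
        assert p == pytest.approx(0.110, abs=5e-4)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_from_table([[0, 0], [5, 5]])
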