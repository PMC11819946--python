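"""OLS fitting, PRESS statistics, standardized coefficients, model search."""

import numpy as np
import pandas as pd
import pytest

from biomimqsar.errors import DomainError, RankError
from biomimqsar.mlr import (
    fit_mlr,
    press_statistics,
    search_models,
    standardized_coefficients,
)


def random_instance(n, p, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 1.0 + X @ beta + rng.normal(0, 0.5, n)
    return X, y


class TestFitMlr:
    def test_exact_linear_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 2))
        y = 3.0 + X @ np.array([1.5, -2.0])
        m = fit_mlr(X, y)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)
        assert m.r2_adj == pytest.approx(1.0, abs=1e-12)
        assert m.sd == pytest.approx(0.0, abs=1e-9)
        assert m.intercept == pytest.approx(3.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        X, y = random_instance(8, 2, seed=42)
        m = fit_mlr(X, y)
        design = np.column_stack([np.ones(8), X])
        beta = np.linalg.inv(design.T @ design) @ design.T @ y
        assert m.intercept == pytest.approx(beta[0], abs=1e-10)
        assert list(m.coef.values()) == pytest.approx(beta[1:], abs=1e-10)
        # coefficient SEs from the explicit OLS covariance
        resid = y - design @ beta
        s2 = resid @ resid / (8 - 3)
        cov = s2 * np.linalg.inv(design.T @ design)
        ses = np.sqrt(np.diag(cov))
        assert m.intercept_se == pytest.approx(ses[0], abs=1e-10)
        assert list(m.coef_se.values()) == pytest.approx(ses[1:], abs=1e-10)

    def test_statistic_definitions(self):
        X, y = random_instance(20, 3, seed=1)
        m = fit_mlr(X, y)
        design = np.column_stack([np.ones(20), X])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ beta) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        assert m.sd == pytest.approx(np.sqrt(rss / (20 - 3 - 1)), rel=1e-10)
        assert m.mse == pytest.approx(rss / 20, rel=1e-10)
        assert m.r2 == pytest.approx(1 - rss / sst, rel=1e-10)
        assert m.r2_adj == pytest.approx(1 - (1 - m.r2) * 19 / 16, rel=1e-10)

    def test_predictor_permutation_invariance(self):
        X, y = random_instance(15, 3, seed=9)
        Xdf = pd.DataFrame(X, columns=list("abc"))
        m1 = fit_mlr(Xdf, y)
        m2 = fit_mlr(Xdf[["c", "a", "b"]], y)
        for name in "abc":
            assert m1.coef[name] == pytest.approx(m2.coef[name], abs=1e-12)
        assert m1.r2 == pytest.approx(m2.r2, abs=1e-12)
        assert m1.press == pytest.approx(m2.press, rel=1e-10)

    def test_predictor_rescaling_transforms_coefficients(self):
        X, y = random_instance(15, 2, seed=10)
        Xdf = pd.DataFrame(X, columns=["a", "b"])
        m1 = fit_mlr(Xdf, y)
        scaled = Xdf.copy()
        scaled["a"] = 10.0 * scaled["a"]
        m2 = fit_mlr(scaled, y)
        assert m2.coef["a"] == pytest.approx(m1.coef["a"] / 10.0, rel=1e-10)
        assert m2.std_coef["a"] == pytest.approx(m1.std_coef["a"], rel=1e-10)

    def test_too_few_observations(self):
        with pytest.raises(DomainError):
            fit_mlr(np.ones((3, 2)) + np.arange(6).reshape(3, 2), np.arange(3.0))

    def test_rank_deficiency_names_columns(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": np.arange(10.0) ** 2})
        with pytest.raises(RankError, match="a, b"):
            fit_mlr(X, np.arange(10.0))


class TestStandardizedCoefficients:
    def test_univariate_equals_pearson_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        y = 0.7 * x + rng.normal(size=12)
        m = fit_mlr(x[:, None], y)
        r = np.corrcoef(x, y)[0, 1]
        assert standardized_coefficients(m, x[:, None], y)[0] == pytest.approx(r, rel=1e-10)

    def test_zscored_inputs_give_raw_coefficients(self):
        X, y = random_instance(14, 2, seed=6)
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        m = fit_mlr(Xz, yz)
        np.testing.assert_allclose(
            standardized_coefficients(m, Xz, yz), list(m.coef.values()), rtol=1e-10
        )

    def test_matches_zscore_refit_oracle(self):
        X, y = random_instance(10, 3, seed=8)
        m = fit_mlr(X, y)
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        refit = fit_mlr(Xz, yz)
        np.testing.assert_allclose(
            standardized_coefficients(m, X, y), list(refit.coef.values()), atol=1e-10
        )

    def test_zero_variance_response_errors(self):
        X, _ = random_instance(10, 2, seed=3)
        with pytest.raises(DomainError):
            fit_mlr(X, np.ones(10))


class TestPressStatistics:
    def test_shortcut_equals_explicit_loo(self):
        for seed in range(10):
            X, y = random_instance(12, 2, seed=seed)
            m = fit_mlr(X, y)
            press, r2_pred, q2 = press_statistics(m, X, y)
            assert press == pytest.approx(m.press, rel=1e-12)
            assert q2 == pytest.approx(r2_pred, rel=1e-10)

    def test_near_exact_fit_has_press_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        y = 1.0 + X @ np.array([2.0, -1.0]) + rng.normal(0, 1e-6, 40)
        m = fit_mlr(X, y)
        assert m.press == pytest.approx(0.0, abs=1e-8)
        assert m.r2_pred == pytest.approx(1.0, abs=1e-8)

    def test_press_at_least_rss(self):
        for seed in range(10):
            X, y = random_instance(15, 3, seed=100 + seed)
            m = fit_mlr(X, y)
            rss = float(np.sum(m.residuals**2))
            assert m.press >= rss - 1e-12
            assert m.r2_pred <= m.r2


class TestSearchModels:
    @staticmethod
    def planted_frame(n=29, sigma=0.05, seed=0):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "x3": rng.normal(size=n),
            }
        )
        frame["y"] = 1.0 + 2.0 * frame.x1 - 1.0 * frame.x2 + rng.normal(0, sigma, n)
        return frame

    def test_single_candidate_is_rank_one(self):
        frame = self.planted_frame()
        res = search_models(frame, "y", [("x1",)])
        assert len(res.models) == 1
        assert res.best.predictors == ["x1"]

    def test_true_superset_of_nested_candidate_ranks_first(self):
        frame = self.planted_frame()
        res = search_models(frame, "y", [("x1",), ("x1", "x2")])
        assert res.best.predictors == ["x1", "x2"]
        assert res.models[0].r2_adj >= res.models[1].r2_adj

    def test_ranking_is_total_and_deterministic(self):
        frame = self.planted_frame()
        cands = [("x1",), ("x2",), ("x3",), ("x1", "x2"), ("x1", "x3"), ("x2", "x3")]
        r1 = search_models(frame, "y", cands)
        r2 = search_models(frame, "y", list(reversed(cands)))
        assert [m.predictors for m in r1.models] == [m.predictors for m in r2.models]
        assert r1.candidate_count == 6

    def test_complete_case_fitting(self):
        frame = self.planted_frame()
        frame.loc[0, "y"] = np.nan
        res = search_models(frame, "y", [("x1", "x2")])
        assert res.best.n == len(frame) - 1

    def test_no_fittable_candidate_errors(self):
        frame = self.planted_frame(n=4)
        with pytest.raises(DomainError):
            search_models(frame, "y", [("x1", "x2", "x3")])

    def test_coefficients_recovered_within_three_se(self):
        """n=29, p=3, sigma=0.1: pooled 3-SE coverage >= 99% over 500 seeded fits."""
        hits = total = 0
        beta = np.array([2.0, -1.0, 0.5])
        for seed in range(500):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(29, 3))
            y = 1.0 + X @ beta + rng.normal(0, 0.1, 29)
            m = fit_mlr(X, y)
            for j, name in enumerate(m.predictors):
                hits += abs(m.coef[name] - beta[j]) <= 3 * m.coef_se[name]
                total += 1
        assert hits / total >= 0.99
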