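"""Regression layer: closed forms, oracle equivalence, invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from crcpath.glm import (SeparationError, build_design, fit_logistic, fit_ols,
                         select_mediators, select_significant_terms)


def _toy_frame(n=400, seed=0, beta=(0.3, 0.5, -0.4)):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    eta = beta[0] + beta[1] * x1 + beta[2] * x2
    y = (rng.random(n) < expit(eta)).astype(float)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2})


class TestLogistic:
    def test_intercept_only_closed_form(self):
        df = _toy_frame(500, seed=1)
        fit = fit_logistic(df, "y", [])
        p = df["y"].mean()
        assert fit.terms["const"].beta == pytest.approx(
            math.log(p / (1 - p)), abs=1e-8)
        assert fit.likelihood_ratio == pytest.approx(0.0, abs=1e-8)
        assert fit.dependent_mean == pytest.approx(p)
        assert fit.n_events == int(df["y"].sum())

    def test_or_equals_exp_beta_and_ci_consistency(self):
        fit = fit_logistic(_toy_frame(), "y", ["x1", "x2"])
        for t in fit.terms.values():
            assert t.or_ == pytest.approx(math.exp(t.beta), rel=1e-12)
            assert t.or_ci[0] == pytest.approx(math.exp(t.ci_low), rel=1e-12)

    def test_full_model_likelihood_dominates_null(self):
        fit = fit_logistic(_toy_frame(), "y", ["x1", "x2"])
        assert fit.likelihood_ratio >= 0.0
        assert fit.score_chi2 >= 0.0

    def test_matches_independent_numeric_oracle(self):
        """MLE agrees to 4 decimals with a hand-written negative
        log-likelihood minimized by BFGS."""
        df = _toy_frame(50, seed=3)
        fit = fit_logistic(df, "y", ["x1", "x2"])
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        y = df["y"].to_numpy()

        def nll(b):
            eta = X @ b
            return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

        res = minimize(nll, np.zeros(3), method="BFGS",
                       options={"gtol": 1e-10})
        est = [fit.terms[k].beta for k in ("const", "x1", "x2")]
        assert np.allclose(est, res.x, atol=1e-4)

    def test_perfect_separation_detected(self):
        n = 60
        x = np.linspace(-2, 2, n)
        df = pd.DataFrame({"y": (x > 0).astype(float), "x1": x})
        with pytest.raises(SeparationError):
            fit_logistic(df, "y", ["x1"])

    def test_degenerate_outcome_rejected(self):
        df = _toy_frame()
        df["y"] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            fit_logistic(df, "y", ["x1"])

    def test_missing_outcome_rows_excluded(self):
        df = _toy_frame(300, seed=5)
        df.loc[:49, "y"] = np.nan
        fit = fit_logistic(df, "y", ["x1"])
        assert fit.n_used == 250


class TestOLS:
    def test_exact_linear_zero_noise(self):
        df = pd.DataFrame({"a": [0.0, 1, 0, 1, 0, 1], "b": [0.0, 0, 1, 1, 0, 1]})
        df["y"] = 2.0 + 3.0 * df["a"] - 1.5 * df["b"]
        fit = fit_ols(df, "y", ["a", "b"])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.terms["a"].beta == pytest.approx(3.0, abs=1e-10)
        assert fit.terms["const"].beta == pytest.approx(2.0, abs=1e-10)

    def test_all_zero_predictor_degrades_to_intercept_mean(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 6.0], "z": [0.0, 0, 0, 0]})
        fit = fit_ols(df, "y", ["z"])
        assert "z" in fit.dropped
        assert fit.terms["const"].beta == pytest.approx(3.0)

    def test_rank_deficiency_reported(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4, 5],
                           "a": [1.0, 2, 3, 4, 5],
                           "b": [2.0, 4, 6, 8, 10]})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_ols(df, "y", ["a", "b"])

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"a": rng.normal(size=200),
                           "b": rng.normal(size=200)})
        df["y"] = 1 + df["a"] - 2 * df["b"] + rng.normal(size=200)
        fit = fit_ols(df, "y", ["a", "b"])
        X = build_design(df, ["a", "b"]).to_numpy()
        resid = df["y"].to_numpy() - X @ np.array(
            [fit.terms["const"].beta, fit.terms["a"].beta, fit.terms["b"].beta])
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_adjusted_r2_below_r2(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["y"] = df["a"] + rng.normal(size=50)
        fit = fit_ols(df, "y", ["a"])
        assert 0.0 <= fit.adj_r2 <= fit.r2 <= 1.0


class TestSelection:
    def test_wald_duality_ci_excludes_null(self):
        df = _toy_frame(2_000, seed=11)
        fit = fit_logistic(df, "y", ["x1", "x2"])
        selected = select_significant_terms(fit, alpha=0.05)
        for name, t in fit.terms.items():
            if name == "const":
                continue
            excludes_zero = t.ci_low > 0 or t.ci_high < 0
            assert (name in selected) == excludes_zero

    def test_mediator_selection_uses_exposure_term(self):
        fits = {}
        for i, b in enumerate((1.2, 0.0)):
            rng = np.random.default_rng(i)
            obese = (rng.random(3_000) < 0.3).astype(float)
            y = (rng.random(3_000) < expit(-2 + b * obese)).astype(float)
            fits[f"m{i}"] = fit_logistic(
                pd.DataFrame({"y": y, "obese": obese}), "y", ["obese"])
        assert select_mediators(fits, term="obese") == ["m0"]


def test_categorical_design_uses_reference_levels(small_cohort):
    X = build_design(small_cohort.head(500),
                     ["obese", "race", "income_quartile", "elective"])
    assert "race_white" not in X.columns and "race_black" in X.columns
    assert "income_Q1" not in X.columns and "income_Q4" in X.columns
    assert X["const"].eq(1.0).all()


def test_parameter_recovery_modest_n(small_cohort):
    """Obesity log-odds on infection recovered within 3 SE at n ~= 30k."""
    fit = fit_logistic(small_cohort, "c_infection",
                       ["obese", "race", "income_quartile", "elective",
                        "urban", "teaching"])
    t = fit.terms["obese"]
    assert abs(t.beta - 0.43) < 3 * t.se
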