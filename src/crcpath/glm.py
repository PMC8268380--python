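"""Regression layer: multivariable logistic models (complication ~ obesity +
covariates; death ~ five complications) and OLS (LOS, charges ~ five
complications), reporting the publication-shaped statistics: coefficient ß,
OR = exp(ß) with Wald 95% CI, event count N, dependent-variable mean,
-2 log L, likelihood-ratio statistic, and a model chi-square (Rao score
test) -- plus R^2 / adjusted R^2 on the OLS side.

Estimation is maximum likelihood via statsmodels (Newton-Raphson, score
tolerance 1e-8, at most 100 iterations); every model is complete-case in its
own outcome.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

CATEGORICAL_LEVELS = {
    "race": ("white", "black", "hispanic", "asian_pi", "other"),
    "income_quartile": ("Q1", "Q2", "Q3", "Q4"),
    "bed_size": ("small", "medium", "large"),
    "age_group": ("20-44", "45-59", "60-74", "75+"),
}
#: reference level = first entry of each tuple above (omitted from the design)
DUMMY_PREFIX = {"income_quartile": "income"}


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    """Newton iterations did not converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class TermEstimate:
    """One coefficient row."""
    beta: float
    se: float
    p_value: float
    ci_low: float            # on the coefficient scale
    ci_high: float
    or_: float | None = None         # exp(beta), logistic only
    or_ci: tuple | None = None       # exponentiated Wald CI


@dataclass
class LogisticFit:
    outcome: str
    terms: dict[str, TermEstimate]
    n_used: int
    n_events: int
    dependent_mean: float
    minus2_log_likelihood: float
    likelihood_ratio: float          # 2 (logL_full - logL_null)
    lr_p: float
    score_chi2: float                # Rao score statistic vs intercept-only
    converged: bool = True
    dropped: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, t in self.terms.items():
            rows.append({"term": name, "beta": t.beta, "se": t.se,
                         "or": t.or_, "or_ci_low": t.or_ci[0],
                         "or_ci_high": t.or_ci[1], "p_value": t.p_value})
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["terms"] = {k: asdict(v) for k, v in self.terms.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class OLSFit:
    outcome: str
    terms: dict[str, TermEstimate]
    n_used: int
    r2: float
    adj_r2: float
    dropped: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, t in self.terms.items():
            rows.append({"term": name, "beta": t.beta, "se": t.se,
                         "ci_low": t.ci_low, "ci_high": t.ci_high,
                         "p_value": t.p_value})
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["terms"] = {k: asdict(v) for k, v in self.terms.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def build_design(rows: pd.DataFrame, predictors) -> pd.DataFrame:
    """Design matrix with intercept column ``const`` first.

    Categorical variables expand to treatment-coded dummies with the
    reference level (first of :data:`CATEGORICAL_LEVELS`) omitted; dummy
    columns are named ``<prefix>_<level>`` (``race_black``, ``income_Q2``).
    Binary/numeric predictors enter as-is.
    """
    X = pd.DataFrame(index=rows.index)
    X["const"] = 1.0
    for var in predictors:
        if var in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[var]
            prefix = DUMMY_PREFIX.get(var, var)
            for lvl in levels[1:]:
                X[f"{prefix}_{lvl}"] = (rows[var] == lvl).astype(float)
        else:
            X[var] = rows[var].astype(float)
    return X


def _drop_constant(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove non-intercept columns with zero variance (e.g. a complication
    flag that never occurs in the estimation sample); the model degrades to
    the remaining terms instead of failing on a trivially singular design."""
    dropped = [c for c in X.columns
               if c != "const" and X[c].nunique() == 1]
    return X.drop(columns=dropped), dropped


def _wald(params, bse, alpha=0.05):
    z = stats.norm.ppf(1 - alpha / 2)
    return params - z * bse, params + z * bse


def _score_test(y: np.ndarray, X: np.ndarray) -> float:
    """Rao score statistic of the full logistic model against the
    intercept-only model, evaluated at the null fit p0 = mean(y)."""
    p0 = y.mean()
    u = X.T @ (y - p0)
    info = p0 * (1 - p0) * (X.T @ X)
    return float(u @ np.linalg.solve(info, u))


def fit_logistic(rows: pd.DataFrame, outcome: str, predictors,
                 alpha_ci: float = 0.05) -> LogisticFit:
    """Maximum-likelihood logistic regression, complete-case in ``outcome``.

    Raises :class:`SeparationError` on perfect separation and
    :class:`ConvergenceError` (with the iteration trace) if Newton-Raphson
    fails to converge within 100 iterations at score tolerance 1e-8.
    """
    data = rows.dropna(subset=[outcome])
    y = data[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} is degenerate (single class)")
    X, dropped = _drop_constant(build_design(data, predictors))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # convergence reported explicitly
            model = sm.Logit(y, X)
            res = model.fit(disp=0, method="newton", tol=1e-8, maxiter=100,
                            full_output=True)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            f"model for {outcome!r}: {exc}") from exc
    if not np.isfinite(res.params).all() or (np.abs(res.params) > 30).any():
        raise SeparationError(
            f"model for {outcome!r}: diverging coefficients suggest separation")
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"model for {outcome!r} did not converge in 100 iterations",
            trace=res.mle_retvals)

    lo, hi = _wald(res.params, res.bse, alpha_ci)
    terms = {
        name: TermEstimate(
            beta=float(res.params[name]), se=float(res.bse[name]),
            p_value=float(res.pvalues[name]),
            ci_low=float(lo[name]), ci_high=float(hi[name]),
            or_=float(np.exp(res.params[name])),
            or_ci=(float(np.exp(lo[name])), float(np.exp(hi[name]))),
        )
        for name in X.columns
    }
    lr = float(2.0 * (res.llf - res.llnull))
    df_model = X.shape[1] - 1
    return LogisticFit(
        outcome=outcome,
        terms=terms,
        n_used=int(len(y)),
        n_events=int(y.sum()),
        dependent_mean=float(y.mean()),
        minus2_log_likelihood=float(-2.0 * res.llf),
        likelihood_ratio=lr,
        lr_p=float(stats.chi2.sf(lr, df_model)) if df_model else 1.0,
        score_chi2=_score_test(y, X.to_numpy()),
        converged=True,
        dropped=dropped,
    )


def fit_ols(rows: pd.DataFrame, outcome: str, predictors,
            alpha_ci: float = 0.05) -> OLSFit:
    """Ordinary least squares with Wald CIs, complete-case in ``outcome``.

    Rank-deficient designs are rejected (reported, not silently dropped).
    """
    data = rows.dropna(subset=[outcome])
    y = data[outcome].to_numpy(dtype=float)
    X, dropped = _drop_constant(build_design(data, predictors))
    if len(y) < X.shape[1] + 1:
        raise ValueError(f"too few complete rows ({len(y)}) for "
                         f"{X.shape[1]} parameters")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"rank-deficient design for {outcome!r}")

    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=alpha_ci)
    terms = {
        name: TermEstimate(
            beta=float(res.params[name]), se=float(res.bse[name]),
            p_value=float(res.pvalues[name]),
            ci_low=float(ci.loc[name, 0]), ci_high=float(ci.loc[name, 1]),
        )
        for name in X.columns
    }
    return OLSFit(outcome=outcome, terms=terms, n_used=int(len(y)),
                  r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
                  dropped=dropped)


def select_significant_terms(fit: LogisticFit, alpha: float = 0.05,
                             exclude=("const",)) -> list[str]:
    """Terms with two-sided Wald p below ``alpha`` (intercept excluded)."""
    return [name for name, t in fit.terms.items()
            if name not in exclude and t.p_value < alpha]


def select_mediators(fits: dict[str, LogisticFit], term: str = "obese",
                     alpha: float = 0.05) -> list[str]:
    """Complications whose exposure coefficient is significant: these are the
    mediators carried into the path analysis."""
    return [name for name, fit in fits.items()
            if fit.terms[term].p_value < alpha]
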