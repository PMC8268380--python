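"""Group comparisons: Pearson chi-square for categorical variables, pooled
two-sample t for continuous ones, with per-outcome missing accounting.

These are the tests behind the cohort-characteristics and outcomes tables.
No multiplicity adjustment is applied.  The t-test defaults to the classical
pooled-variance form (group SDs in the motivating data are near-equal) but
Welch's form is available via ``equal_var=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    """One table row: a variable compared between two groups."""
    variable: str
    test: str                      # "pearson_chi2" | "t"
    statistic: float
    p_value: float
    df: float
    groups: dict = field(default_factory=dict)   # per-group summaries
    n_missing: dict = field(default_factory=dict)
    warning: str | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compare_categorical(counts, variable: str = "",
                        group_names=("group0", "group1"),
                        level_names=None) -> GroupComparison:
    """Pearson chi-square on a 2 x k contingency table (no continuity
    correction; large samples throughout).

    ``counts`` is array-like with groups on rows and levels on columns.
    Identical distributions give statistic 0, p = 1.  A warning string is
    attached when any expected count is below 5.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError(f"expected a 2 x k table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (table.sum(axis=1) <= 0).any() or (table.sum(axis=0) <= 0).any():
        raise ValueError("zero margin in contingency table")

    k = table.shape[1]
    if k == 1:
        stat, p, dof = 0.0, 1.0, 0
        expected = table
    else:
        stat, p, dof, expected = stats.chi2_contingency(table, correction=False)
    warning = None
    if (expected < 5).any():
        warning = "expected cell count < 5; chi-square approximation is poor"

    levels = level_names or [str(i) for i in range(k)]
    groups = {}
    for g, name in enumerate(group_names):
        total = table[g].sum()
        groups[name] = {
            "counts": dict(zip(levels, table[g].astype(int).tolist())),
            "percent": {l: 100.0 * c / total
                        for l, c in zip(levels, table[g].tolist())},
            "n": int(total),
        }
    return GroupComparison(variable=variable, test="pearson_chi2",
                           statistic=float(stat), p_value=float(p),
                           df=float(dof), groups=groups, warning=warning)


def compare_continuous(x0, x1, variable: str = "",
                       group_names=("group0", "group1"),
                       equal_var: bool = True) -> GroupComparison:
    """Two-sample t-test; missing values (NaN) are excluded and counted.

    Degenerate input (zero variance in both groups with equal means) returns
    t = 0, p = 1 rather than NaN.
    """
    a0 = np.asarray(x0, dtype=float)
    a1 = np.asarray(x1, dtype=float)
    miss = {group_names[0]: int(np.isnan(a0).sum()),
            group_names[1]: int(np.isnan(a1).sum())}
    a0 = a0[~np.isnan(a0)]
    a1 = a1[~np.isnan(a1)]
    if len(a0) < 2 or len(a1) < 2:
        raise ValueError("need >= 2 non-missing values per group")

    if a0.var(ddof=1) == 0 and a1.var(ddof=1) == 0 and a0.mean() == a1.mean():
        t, p = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = stats.ttest_ind(a0, a1, equal_var=equal_var)
        if np.isnan(p):
            t, p = 0.0, 1.0
    dof = (len(a0) + len(a1) - 2) if equal_var else float("nan")

    groups = {}
    for arr, name in ((a0, group_names[0]), (a1, group_names[1])):
        groups[name] = {"n": int(len(arr)), "mean": float(arr.mean()),
                        "sd": float(arr.std(ddof=1)),
                        "median": float(np.median(arr))}
    return GroupComparison(variable=variable, test="t", statistic=float(t),
                           p_value=float(p), df=float(dof), groups=groups,
                           n_missing=miss)


# ---------------------------------------------------------------------------
# table builders over an analytic cohort
# ---------------------------------------------------------------------------

CATEGORICAL_VARS = ("sex", "age_group", "race", "income_quartile", "elective",
                    "metastasis", "alcohol_abuse", "diabetes", "liver_disease",
                    "bed_size", "urban", "teaching")


def characteristics_table(rows: pd.DataFrame, exposure: str = "obese",
                          variables=CATEGORICAL_VARS) -> list[GroupComparison]:
    """Cohort-characteristics comparisons (one chi-square per covariate)."""
    out = []
    g0 = rows[rows[exposure] == 0]
    g1 = rows[rows[exposure] == 1]
    for var in variables:
        levels = sorted(rows[var].dropna().unique(), key=str)
        counts = [[int((g[var] == lvl).sum()) for lvl in levels]
                  for g in (g0, g1)]
        out.append(compare_categorical(
            counts, variable=var, group_names=("non_obese", "obese"),
            level_names=[str(l) for l in levels]))
    return out


def outcomes_table(rows: pd.DataFrame, exposure: str = "obese",
                   complications=None) -> list[GroupComparison]:
    """Outcome comparisons: death + each complication (chi-square), LOS and
    charges (t-test), with per-outcome missing counts."""
    from .published import COMPLICATIONS
    complications = complications or COMPLICATIONS
    out = []
    g0 = rows[rows[exposure] == 0]
    g1 = rows[rows[exposure] == 1]

    died = [g["died"].dropna() for g in (g0, g1)]
    cmp_death = compare_categorical(
        [[int((d == 0).sum()), int((d == 1).sum())] for d in died],
        variable="died", group_names=("non_obese", "obese"),
        level_names=["alive", "died"])
    cmp_death.n_missing = {"non_obese": int(g0["died"].isna().sum()),
                           "obese": int(g1["died"].isna().sum())}
    out.append(cmp_death)

    for comp in complications:
        col = f"c_{comp}"
        counts = [[int((g[col] == 0).sum()), int((g[col] == 1).sum())]
                  for g in (g0, g1)]
        out.append(compare_categorical(
            counts, variable=col, group_names=("non_obese", "obese"),
            level_names=["no", "yes"]))

    for col in ("los_days", "total_charges"):
        out.append(compare_continuous(
            g0[col].to_numpy(), g1[col].to_numpy(), variable=col,
            group_names=("non_obese", "obese")))
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flat CSV-ready view of a comparison list."""
    rows = []
    for c in comparisons:
        row = {"variable": c.variable, "test": c.test,
               "statistic": c.statistic, "p_value": c.p_value, "df": c.df,
               "significant": c.significant}
        for g, summ in c.groups.items():
            for k, v in summ.items():
                if isinstance(v, dict):
                    for lvl, val in v.items():
                        row[f"{g}.{k}.{lvl}"] = val
                else:
                    row[f"{g}.{k}"] = v
        for g, n in c.n_missing.items():
            row[f"{g}.n_missing"] = n
        rows.append(row)
    return pd.DataFrame(rows)
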