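"""1:k exact case-control matching on (age band, sex, metastasis).

Each obese case receives ``ratio`` non-obese controls drawn uniformly
without replacement from the controls sharing its full stratum key; no
control is reused.  Cases whose stratum runs out of controls are reported
unmatched and excluded.  Case processing order is shuffled by the seed, so
which cases lose out in a tight stratum is random but reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_KEY = ("age_group", "sex", "metastasis")


@dataclass
class MatchedCohort:
    """Result of exact 1:k matching over analytic rows."""
    key: tuple[str, ...]
    ratio: int
    seed: int
    pairs: dict[str, list[str]] = field(default_factory=dict)   # case -> controls
    unmatched: list[str] = field(default_factory=list)
    strata: dict[tuple, dict] = field(default_factory=dict)     # key -> counts

    @property
    def case_ids(self) -> list[str]:
        return list(self.pairs)

    @property
    def control_ids(self) -> list[str]:
        return [c for ctrls in self.pairs.values() for c in ctrls]

    def matched_ids(self) -> list[str]:
        return self.case_ids + self.control_ids

    def to_dataframe(self) -> pd.DataFrame:
        """Long form: one row per (case, control) pair with the stratum key."""
        rows = []
        for case, ctrls in self.pairs.items():
            for ctrl in ctrls:
                rows.append({"case_id": case, "control_id": ctrl,
                             "stratum": self._stratum_of.get(case)})
        return pd.DataFrame(rows, columns=["case_id", "control_id", "stratum"])

    def to_json(self, path) -> None:
        payload = {
            "key": list(self.key), "ratio": self.ratio, "seed": self.seed,
            "n_cases_matched": len(self.pairs),
            "n_unmatched": len(self.unmatched),
            "pairs": self.pairs, "unmatched": self.unmatched,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    _stratum_of: dict = field(default_factory=dict, repr=False)


def match_1to4(rows: pd.DataFrame,
               key: tuple[str, ...] = DEFAULT_KEY,
               ratio: int = 4,
               seed: int = 0,
               exposure: str = "obese",
               id_col: str = "record_id") -> MatchedCohort:
    """Exact stratified 1:``ratio`` matching of exposed cases to controls.

    Within each stratum both the case order and the control pool are
    shuffled by ``seed``; controls are then assigned in blocks of ``ratio``,
    which is equivalent to uniform sampling without replacement.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    for col in (exposure, id_col, *key):
        if col not in rows.columns:
            raise ValueError(f"matching requires column {col!r}")

    rng = np.random.default_rng(seed)
    out = MatchedCohort(key=tuple(key), ratio=ratio, seed=seed)

    exposed = rows[rows[exposure] == 1]
    unexposed = rows[rows[exposure] == 0]
    if exposed.empty or unexposed.empty:
        raise ValueError("matching needs both exposed and unexposed rows")

    case_groups = {k: g[id_col].tolist() for k, g in exposed.groupby(list(key))}
    ctrl_groups = {k: g[id_col].tolist() for k, g in unexposed.groupby(list(key))}

    # deterministic stratum iteration order
    for stratum in sorted(case_groups, key=str):
        cases = np.array(case_groups[stratum], dtype=object)
        ctrls = np.array(ctrl_groups.get(stratum, []), dtype=object)
        rng.shuffle(cases)
        rng.shuffle(ctrls)
        n_fit = min(len(cases), len(ctrls) // ratio)
        for i, case in enumerate(cases):
            if i < n_fit:
                out.pairs[case] = list(ctrls[i * ratio:(i + 1) * ratio])
                out._stratum_of[case] = "|".join(map(str, stratum))
            else:
                out.unmatched.append(case)
        out.strata[stratum] = {
            "cases": len(cases), "controls": len(ctrls), "matched": int(n_fit)
        }
    return out


def matched_rows(rows: pd.DataFrame, matched: MatchedCohort,
                 id_col: str = "record_id") -> pd.DataFrame:
    """The analytic subset entering all downstream analyses (cases first).

    Matching never alters any row's fields; it only selects.
    """
    order = matched.matched_ids()
    sub = rows.set_index(id_col).loc[order].reset_index()
    return sub
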