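"""Cohort extraction: inclusion/exclusion rules and analytic-flag derivation.

Inclusion rules, applied in order (each record is counted against the first
rule it fails, mirroring a selection flow diagram):

1. age >= 20 years
2. at least one colorectal-cancer diagnosis code (roots 153, 154)
3. at least one qualifying resection procedure code
4. no other-cancer diagnosis in 140-239 (colorectal and secondary-malignancy
   roots carved out)

The analytic row carries the exposure (obesity, dx 278.0), severity
(metastasis, secondary-malignancy dx), comorbidity and complication flags --
all derived solely from the diagnosis codes via the :class:`CodeBook` -- plus
demographics, hospital attributes and the three outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import CodeBook, DEFAULT_CODEBOOK
from .records import InpatientRecord

RULES = ("age_under_20", "no_crc_dx", "no_surgery_proc", "other_cancer_dx")

#: analytic column order (complications carry a ``c_`` prefix)
from .published import COMPLICATIONS


@dataclass
class AttritionLog:
    """Counts removed per inclusion rule, in rule order."""
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_kept: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_input": self.n_input, "removed": self.removed,
                       "n_kept": self.n_kept}, fh, indent=2)


def _age_group(age: int) -> str:
    if age <= 44:
        return "20-44"
    if age <= 59:
        return "45-59"
    if age <= 74:
        return "60-74"
    return "75+"


def filter_records(records: list[InpatientRecord],
                   codebook: CodeBook = DEFAULT_CODEBOOK,
                   ) -> tuple[list[InpatientRecord], AttritionLog]:
    """Apply the inclusion rules; idempotent (a second pass removes nothing)."""
    log = AttritionLog(n_input=len(records), removed={r: 0 for r in RULES})
    kept = []
    for rec in records:
        if rec.age_years < 20:
            log.removed["age_under_20"] += 1
        elif not any(codebook.is_crc(d) for d in rec.dx_codes):
            log.removed["no_crc_dx"] += 1
        elif not any(codebook.is_surgery(p) for p in rec.proc_codes):
            log.removed["no_surgery_proc"] += 1
        elif any(codebook.is_other_cancer(d) for d in rec.dx_codes):
            log.removed["other_cancer_dx"] += 1
        else:
            kept.append(rec)
    log.n_kept = len(kept)
    return kept, log


def derive_rows(records: list[InpatientRecord],
                codebook: CodeBook = DEFAULT_CODEBOOK) -> pd.DataFrame:
    """Derive one analytic row per (already-included) record."""
    rows = []
    for rec in records:
        row = {
            "record_id": rec.record_id,
            "obese": int(any(codebook.is_obesity(d) for d in rec.dx_codes)),
            "age_group": _age_group(rec.age_years),
            "age_years": rec.age_years,
            "sex": rec.sex,
            "metastasis": int(any(codebook.is_metastasis(d) for d in rec.dx_codes)),
            "race": rec.race,
            "income_quartile": rec.income_quartile,
            "elective": int(rec.elective),
            "bed_size": rec.bed_size,
            "urban": int(rec.urban),
            "teaching": int(rec.teaching),
        }
        row.update({k: int(v) for k, v in
                    codebook.comorbidity_flags(rec.dx_codes).items()})
        comp = codebook.complication_flags(rec.dx_codes)
        row.update({f"c_{k}": int(comp[k]) for k in COMPLICATIONS})
        row["died"] = np.nan if rec.died is None else float(rec.died)
        row["los_days"] = np.nan if rec.los_days is None else float(rec.los_days)
        row["total_charges"] = (np.nan if rec.total_charges is None
                                else float(rec.total_charges))
        rows.append(row)
    return pd.DataFrame(rows)


def extract_cohort(records: list[InpatientRecord],
                   codebook: CodeBook = DEFAULT_CODEBOOK,
                   ) -> tuple[pd.DataFrame, AttritionLog]:
    """Inclusion rules + analytic-flag derivation in one call."""
    kept, log = filter_records(records, codebook)
    return derive_rows(kept, codebook), log
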