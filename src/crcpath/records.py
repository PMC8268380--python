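"""Admission-level records and their CSV round-trip.

The on-disk layout is one row per admission; diagnosis and procedure code
lists are semicolon-delimited within single columns; an empty cell in an
outcome column (``died``, ``los_days``, ``total_charges``) means missing.
A machine-readable data dictionary (JSON) is written next to every CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .codes import is_valid_icd9


class RecordIOError(ValueError):
    """Malformed rows on read; carries (line_number, message) pairs."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in problems[:10])
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        super().__init__(f"{len(problems)} malformed row(s): {lines}{more}")


@dataclass
class InpatientRecord:
    """One hospital admission, as the claims file would carry it."""

    record_id: str
    dx_codes: list[str]
    proc_codes: list[str]
    age_years: int
    sex: str                    # male / female
    race: str                   # white / black / hispanic / asian_pi / other
    income_quartile: str        # Q1..Q4
    elective: bool
    bed_size: str               # small / medium / large
    urban: bool
    teaching: bool
    died: bool | None = None            # None = missing
    los_days: float | None = None
    total_charges: float | None = None
    missing: dict = field(default_factory=dict)  # reserved for extra flags

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if the record is ok)."""
        problems = []
        for c in self.dx_codes + self.proc_codes:
            if not is_valid_icd9(c):
                problems.append(f"invalid ICD-9 code {c!r}")
        if self.los_days is not None and (
            math.isnan(self.los_days) or self.los_days < 0
        ):
            problems.append(f"negative or NaN los_days {self.los_days}")
        if self.total_charges is not None and (
            math.isnan(self.total_charges) or self.total_charges < 0
        ):
            problems.append(f"negative or NaN total_charges {self.total_charges}")
        return problems


_COLUMNS = [
    "record_id", "dx_codes", "proc_codes", "age_years", "sex", "race",
    "income_quartile", "elective", "bed_size", "urban", "teaching",
    "died", "los_days", "total_charges",
]

DATA_DICTIONARY = {
    "record_id": "opaque admission identifier",
    "dx_codes": "ICD-9-CM diagnosis codes, semicolon-delimited",
    "proc_codes": "ICD-9 procedure codes, semicolon-delimited",
    "age_years": "age at admission, integer years",
    "sex": "male | female",
    "race": "white | black | hispanic | asian_pi | other",
    "income_quartile": "ZIP-level median household income quartile Q1 (poorest) .. Q4",
    "elective": "1 = elective admission, 0 = non-elective",
    "bed_size": "hospital bed size: small | medium | large",
    "urban": "1 = urban hospital, 0 = rural",
    "teaching": "1 = teaching hospital",
    "died": "1 = died in hospital, 0 = discharged alive; empty = missing",
    "los_days": "length of stay, days; empty = missing",
    "total_charges": "total hospital charges, US dollars; empty = missing",
}


def write_records(records: list[InpatientRecord], path) -> None:
    """Write records as CSV plus a ``<path>.dict.json`` data dictionary."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id,
            "dx_codes": ";".join(r.dx_codes),
            "proc_codes": ";".join(r.proc_codes),
            "age_years": r.age_years,
            "sex": r.sex,
            "race": r.race,
            "income_quartile": r.income_quartile,
            "elective": int(r.elective),
            "bed_size": r.bed_size,
            "urban": int(r.urban),
            "teaching": int(r.teaching),
            "died": "" if r.died is None else int(r.died),
            "los_days": "" if r.los_days is None else repr(float(r.los_days)),
            "total_charges": "" if r.total_charges is None else repr(float(r.total_charges)),
        })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
    with open(str(path) + ".dict.json", "w") as fh:
        json.dump(DATA_DICTIONARY, fh, indent=2)


def read_records(path) -> list[InpatientRecord]:
    """Read a records CSV; malformed rows raise :class:`RecordIOError` with
    1-based data line numbers (header = line 1).  Blank outcome cells become
    ``None`` (missing), never dropped rows."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise RecordIOError([(1, f"missing columns {missing_cols}")])

    records: list[InpatientRecord] = []
    problems: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header occupies line 1
        try:
            rec = InpatientRecord(
                record_id=row.record_id,
                dx_codes=[c for c in row.dx_codes.split(";") if c],
                proc_codes=[c for c in row.proc_codes.split(";") if c],
                age_years=int(row.age_years),
                sex=row.sex,
                race=row.race,
                income_quartile=row.income_quartile,
                elective=bool(int(row.elective)),
                bed_size=row.bed_size,
                urban=bool(int(row.urban)),
                teaching=bool(int(row.teaching)),
                died=None if row.died == "" else bool(int(row.died)),
                los_days=None if row.los_days == "" else float(row.los_days),
                total_charges=None if row.total_charges == "" else float(row.total_charges),
            )
        except (ValueError, TypeError) as exc:
            problems.append((line, str(exc)))
            continue
        bad = rec.validate()
        if bad:
            problems.extend((line, b) for b in bad)
        else:
            records.append(rec)
    if problems:
        raise RecordIOError(problems)
    return records
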