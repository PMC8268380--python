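"""ICD-9-CM code sets defining cohort, exposure, severity, and endpoints.

Codes are matched by string prefix on the normalized (dotless) form, the
standard claims convention: diagnosis ``153.4`` normalizes to ``1534`` and
matches root ``153``; procedure ``45.73`` normalizes to ``4573`` and matches
root ``457`` (the open/subtotal colectomy family 45.7x).  Diagnosis and
procedure codes live in separate namespaces and are never compared across.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import yaml

_ICD9_RE = re.compile(r"^[VE]?\d{2,3}(\.\d{1,2})?$|^[VE]?\d{3,5}$")


def normalize(code: str) -> str:
    """Return the dotless upper-case form of an ICD-9 code string."""
    return code.strip().upper().replace(".", "")


def is_valid_icd9(code: str) -> bool:
    """Syntactic check: 2-3 character root (optionally V/E-prefixed) plus up
    to two decimal digits."""
    return bool(_ICD9_RE.match(code.strip().upper()))


def matches_any(code: str, roots: tuple[str, ...] | list[str]) -> bool:
    """True if the normalized code starts with any normalized root."""
    c = normalize(code)
    return any(c.startswith(normalize(r)) for r in roots)


def numeric_root(code: str) -> int | None:
    """3-digit integer root of a plain numeric dx code, else None (V/E codes)."""
    c = normalize(code)
    if not c[:1].isdigit():
        return None
    return int(c[:3]) if len(c) >= 3 else None


@dataclass(frozen=True)
class CodeBook:
    """Code sets used by cohort extraction and flag derivation.

    Attributes hold *roots*: prefix-matching is applied to each admission's
    code lists.  The other-cancer exclusion is the 3-digit range
    ``cancer_range`` minus the colorectal roots and the secondary-malignancy
    roots that mark metastatic disease (matching on metastasis requires the
    metastasis codes to survive extraction).
    """

    crc_dx: tuple[str, ...] = ("153", "154")
    metastasis_dx: tuple[str, ...] = ("196", "197", "198")
    cancer_range: tuple[int, int] = (140, 239)
    obesity_dx: tuple[str, ...] = ("2780",)
    surgery_proc: tuple[str, ...] = (
        "457",                              # open and subtotal colectomy 45.7x
        "4840", "4841", "4843", "4849",     # pull-through resection of rectum
        "4850", "4852", "4859",             # abdominoperineal resection / proctectomy
        "486",                              # other rectal resections 48.6x
    )
    complication_dx: dict[str, tuple[str, ...]] = field(default_factory=lambda: {
        "infection": ("9985",),
        "shock": ("9980",),
        "bleeding": ("9981",),
        "wound_disruption": ("9983",),
        "nonhealing_wound": ("99883",),
        "nervous": ("9970",),
        "cardiac": ("9971",),
        "phlebitis": ("9972",),
        "respiratory": ("9973",),
        "digestive": ("9974",),
        "urinary": ("9975",),
        "vascular": ("9977",),
        "unspecified": ("9989",),
    })
    comorbidity_dx: dict[str, tuple[str, ...]] = field(default_factory=lambda: {
        "diabetes": ("250",),
        "liver_disease": ("571",),
        "alcohol_abuse": ("303",),
    })

    def __post_init__(self) -> None:
        lo, hi = self.cancer_range
        for name, roots in self.complication_dx.items():
            for r in roots:
                root3 = numeric_root(r + "00")
                if root3 is not None and lo <= root3 <= hi:
                    raise ValueError(
                        f"complication {name!r} root {r} lies inside the "
                        f"cancer exclusion range {lo}-{hi}"
                    )

    # -- semantic predicates -------------------------------------------------

    def is_crc(self, dx: str) -> bool:
        return matches_any(dx, self.crc_dx)

    def is_metastasis(self, dx: str) -> bool:
        return matches_any(dx, self.metastasis_dx)

    def is_obesity(self, dx: str) -> bool:
        return matches_any(dx, self.obesity_dx)

    def is_other_cancer(self, dx: str) -> bool:
        """Inside 140-239 on the 3-digit root, with CRC and secondary-
        malignancy roots carved out."""
        root = numeric_root(dx)
        if root is None:
            return False
        lo, hi = self.cancer_range
        if not (lo <= root <= hi):
            return False
        carved = {int(r) for r in self.crc_dx + self.metastasis_dx}
        return root not in carved

    def is_surgery(self, proc: str) -> bool:
        return matches_any(proc, self.surgery_proc)

    def complication_flags(self, dx_codes: list[str]) -> dict[str, bool]:
        return {
            name: any(matches_any(d, roots) for d in dx_codes)
            for name, roots in self.complication_dx.items()
        }

    def comorbidity_flags(self, dx_codes: list[str]) -> dict[str, bool]:
        return {
            name: any(matches_any(d, roots) for d in dx_codes)
            for name, roots in self.comorbidity_dx.items()
        }

    # -- serialization -------------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CodeBook":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("crc_dx", "metastasis_dx", "obesity_dx", "surgery_proc"):
            if key in raw:
                raw[key] = tuple(str(x) for x in raw[key])
        if "cancer_range" in raw:
            raw["cancer_range"] = tuple(raw["cancer_range"])
        for key in ("complication_dx", "comorbidity_dx"):
            if key in raw:
                raw[key] = {k: tuple(str(x) for x in v) for k, v in raw[key].items()}
        return cls(**raw)


DEFAULT_CODEBOOK = CodeBook()
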