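"""Absolute marginal effects and the exposure -> mediator -> outcome path
decomposition.

For a logistic coefficient ß the *absolute marginal effect* is

    dP/dX = ß · P · (1 − P)

evaluated at the outcome prevalence P (the dependent-variable mean of the
model's estimation sample).  Unlike odds ratios, these absolute effects
multiply along a path: the contribution of mediator *i* to an outcome is
aᵢ·bᵢ where aᵢ is the exposure->mediator marginal effect and bᵢ the
mediator->outcome effect (a marginal probability for death; an OLS
coefficient, in days or dollars, for LOS and charges).  The total indirect
effect is the sum Σ aᵢ·bᵢ over mediators; no direct (non-mediated)
exposure->outcome edge enters the totals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .glm import LogisticFit, OLSFit

OUTCOMES = ("mortality", "los", "charges")


@dataclass(frozen=True)
class MarginalEffect:
    """dP/dX = ß·P·(1−P) for one coefficient at outcome prevalence P."""
    term: str
    beta: float
    p: float
    value: float

    def __post_init__(self):
        # derivative of the logistic mean is bounded by |beta|/4 at P = 1/2
        assert abs(self.value) <= abs(self.beta) / 4 + 1e-15


def marginal_effect(beta: float, p: float, term: str = "") -> MarginalEffect:
    """Evaluate ß·P·(1−P); ``p`` must lie strictly inside (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence must lie in (0,1), got {p}")
    return MarginalEffect(term=term, beta=float(beta), p=float(p),
                          value=float(beta) * float(p) * (1.0 - float(p)))


@dataclass(frozen=True)
class PathEffect:
    """One mediator's edges and products for the three outcomes."""
    mediator: str
    a: float                 # exposure -> mediator, probability
    b_mortality: float       # mediator -> death, probability
    b_los: float             # mediator -> LOS, days
    b_charges: float         # mediator -> charges, USD
    prod_mortality: float = field(init=False)
    prod_los: float = field(init=False)
    prod_charges: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "prod_mortality", self.a * self.b_mortality)
        object.__setattr__(self, "prod_los", self.a * self.b_los)
        object.__setattr__(self, "prod_charges", self.a * self.b_charges)


@dataclass
class PathSummary:
    """The full path decomposition: per-mediator products and totals."""
    effects: list[PathEffect]
    totals: dict[str, float] = field(init=False)
    dominant: dict[str, str] = field(init=False)

    def __post_init__(self):
        self.totals = {
            "mortality": sum(e.prod_mortality for e in self.effects),
            "los": sum(e.prod_los for e in self.effects),
            "charges": sum(e.prod_charges for e in self.effects),
        }
        self.dominant = {
            out: max(self.effects,
                     key=lambda e: abs(getattr(e, f"prod_{out}"))).mediator
            for out in OUTCOMES
        }

    def effect(self, mediator: str) -> PathEffect:
        for e in self.effects:
            if e.mediator == mediator:
                return e
        raise KeyError(mediator)

    # -- serializations ------------------------------------------------------

    def to_dict(self) -> dict:
        return {"effects": [asdict(e) for e in self.effects],
                "totals": self.totals, "dominant": self.dominant}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def edge_list(self) -> dict:
        """Node-edge serialization of the path diagram."""
        nodes = (["obesity"] + [e.mediator for e in self.effects]
                 + ["mortality", "los", "charges"])
        edges = []
        for e in self.effects:
            edges.append({"from": "obesity", "to": e.mediator, "weight": e.a})
            edges.append({"from": e.mediator, "to": "mortality",
                          "weight": e.b_mortality, "path_weight": e.prod_mortality})
            edges.append({"from": e.mediator, "to": "los",
                          "weight": e.b_los, "path_weight": e.prod_los})
            edges.append({"from": e.mediator, "to": "charges",
                          "weight": e.b_charges, "path_weight": e.prod_charges})
        return {"nodes": nodes, "edges": edges}

    def format_table(self) -> str:
        """Human-readable path table in the publication's mixed units:
        mortality products in 1e-5 probability units, LOS in days, charges
        in whole dollars."""
        lines = [f"{'mediator':<18}{'a':>9}{'b_mort':>9}"
                 f"{'a*b mort(1e-5)':>16}{'a*b LOS(d)':>12}{'a*b chg($)':>12}"]
        for e in self.effects:
            lines.append(
                f"{e.mediator:<18}{e.a:>9.4f}{e.b_mortality:>9.4f}"
                f"{e.prod_mortality * 1e5:>16.2f}{e.prod_los:>12.3f}"
                f"{e.prod_charges:>12.0f}")
        lines.append(
            f"{'TOTAL':<18}{'':>9}{'':>9}"
            f"{self.totals['mortality'] * 1e5:>16.2f}"
            f"{self.totals['los']:>12.3f}{self.totals['charges']:>12.0f}")
        return "\n".join(lines)


def build_paths(exposure_effects: dict[str, MarginalEffect],
                mortality_effects: dict[str, MarginalEffect],
                los_fit: OLSFit,
                charges_fit: OLSFit) -> PathSummary:
    """Assemble the decomposition from fitted layers.

    ``exposure_effects``: per-mediator dP/dX of the exposure coefficient in
    each complication model.  ``mortality_effects``: per-mediator dP/dX from
    the death model.  The OLS fits supply the LOS/charges edges directly.
    Mediator name sets must agree across all four layers.
    """
    meds = list(exposure_effects)
    for layer_name, names in (
        ("mortality", set(mortality_effects)),
        ("los", {t for t in los_fit.terms if t != "const"}),
        ("charges", {t for t in charges_fit.terms if t != "const"}),
    ):
        if names != set(meds):
            raise ValueError(
                f"mediator mismatch in {layer_name} layer: "
                f"{sorted(names)} vs {sorted(meds)}")
    effects = [
        PathEffect(
            mediator=m,
            a=exposure_effects[m].value,
            b_mortality=mortality_effects[m].value,
            b_los=los_fit.terms[m].beta,
            b_charges=charges_fit.terms[m].beta,
        )
        for m in meds
    ]
    return PathSummary(effects=effects)


def from_printed_tables(table3: dict[str, dict],
                        table4: dict[str, dict],
                        table5: dict[str, dict]) -> PathSummary:
    """Replay mode: rebuild the decomposition from published coefficients.

    Each table maps mediator -> dict.  ``table3``/``table4`` entries carry
    either a precomputed ``dpdx`` or a (``beta``, ``p``) pair from which
    ß·P·(1−P) is evaluated; ``table5`` entries carry ``los`` and ``charges``
    OLS coefficients.  All three tables must cover the same mediators.
    """
    meds = list(table3)
    if set(table4) != set(meds) or set(table5) != set(meds):
        raise ValueError("mediator sets differ across the three tables")

    def dpdx(entry: dict, term: str) -> float:
        if "dpdx" in entry and entry["dpdx"] is not None:
            return float(entry["dpdx"])
        return marginal_effect(entry["beta"], entry["p"], term).value

    effects = [
        PathEffect(
            mediator=m,
            a=dpdx(table3[m], m),
            b_mortality=dpdx(table4[m], m),
            b_los=float(table5[m]["los"]),
            b_charges=float(table5[m]["charges"]),
        )
        for m in meds
    ]
    return PathSummary(effects=effects)
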