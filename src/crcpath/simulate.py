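"""Synthetic NIS-like admission generator.

The generator draws admissions with the causal structure the downstream
analysis assumes:

    obesity  ->  13 postoperative complications  ->  death, LOS, charges

* Obesity is a Bernoulli exposure; every other covariate is sampled from a
  distribution conditional on obesity status, so published group differences
  (e.g. diabetes 40.7% in the obese vs 18.7% in the non-obese) are
  reproduced without an explicit dependence model.
* Each complication is a Bernoulli draw from a logistic model in obesity and
  the hospital/demographic adjustment covariates; complications are
  conditionally independent given those covariates.
* In-hospital death is a logistic draw in the five mediating complications
  only; length of stay and total charges are linear in the same five flags
  plus mean-zero right-skewed (shifted log-normal) noise, which keeps both
  outcomes positive without clipping.
* Exposure, severity (metastasis), comorbidities, and complications are all
  *encoded as ICD-9-CM codes* on the emitted records, so cohort extraction
  and flag derivation are exercised for real.

By default the generator emits the post-inclusion cohort (every record has a
colorectal-cancer diagnosis, a qualifying resection procedure, age >= 20 and
no other-cancer code); ``distractor_fraction`` injects records violating one
inclusion rule each, to exercise extraction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import published
from .records import InpatientRecord

_GROUPS = ("non_obese", "obese")

AGE_BANDS = {"20-44": (20, 44), "45-59": (45, 59), "60-74": (60, 74), "75+": (75, 100)}

_CRC_CODES = ["153.0", "153.2", "153.3", "153.4", "153.6", "153.9", "154.0", "154.1"]
_MET_CODES = ["196.2", "197.0", "197.7", "198.5"]
_SURG_CODES = ["45.73", "45.75", "45.76", "48.40", "48.41", "48.43", "48.49",
               "48.50", "48.52", "48.59", "48.62", "48.63"]
_COMPLICATION_CODE = {
    "infection": "998.5", "shock": "998.0", "bleeding": "998.1",
    "wound_disruption": "998.3", "nonhealing_wound": "998.83",
    "nervous": "997.0", "cardiac": "997.1", "phlebitis": "997.2",
    "respiratory": "997.3", "digestive": "997.4", "urinary": "997.5",
    "vascular": "997.7", "unspecified": "998.9",
}
_COMORBIDITY_CODE = {"diabetes": "250.00", "liver_disease": "571.5",
                     "alcohol_abuse": "303.90"}


class ConfigError(ValueError):
    """Non-stochastic configuration problem, reported before any sampling."""


@dataclass
class LogisticSpec:
    """Generating logistic model: P(y=1) = expit(intercept + sum(beta * x))."""
    intercept: float
    terms: dict[str, float] = field(default_factory=dict)


@dataclass
class LinearSpec:
    """Generating linear model with shifted log-normal noise.

    The noise is ``LogNormal(mu, sigma) - noise_mean`` with ``(mu, sigma)``
    solved from (noise_mean, noise_sd), hence mean zero, SD ``noise_sd`` and
    support bounded below at ``-noise_mean``.
    """
    intercept: float
    terms: dict[str, float] = field(default_factory=dict)
    noise_mean: float = 1.0
    noise_sd: float = 1.0

    def lognormal_params(self) -> tuple[float, float]:
        if self.noise_mean <= 0 or self.noise_sd <= 0:
            raise ConfigError("noise_mean and noise_sd must be positive")
        sigma2 = np.log1p((self.noise_sd / self.noise_mean) ** 2)
        mu = np.log(self.noise_mean) - sigma2 / 2.0
        return mu, float(np.sqrt(sigma2))


@dataclass
class SimConfig:
    """Full generating configuration for one synthetic cohort."""

    n_patients: int
    obesity_prevalence: float
    covariate_tables: dict[str, dict[str, dict[str, float]]]
    complication_models: dict[str, LogisticSpec]
    mortality_model: LogisticSpec
    los_model: LinearSpec
    charges_model: LinearSpec
    missing_rates: dict[str, float] = field(default_factory=dict)
    distractor_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError(f"n_patients must be >= 0, got {self.n_patients}")
        if not 0.0 < self.obesity_prevalence < 1.0:
            raise ConfigError("obesity_prevalence must lie in (0, 1)")
        for var, groups in self.covariate_tables.items():
            for grp in _GROUPS:
                if grp not in groups:
                    raise ConfigError(f"covariate {var!r} missing group {grp!r}")
                probs = np.array(list(groups[grp].values()), dtype=float)
                if (probs < 0).any():
                    raise ConfigError(f"covariate {var!r}/{grp} has negative mass")
                if abs(probs.sum() - 1.0) > 1e-9:
                    raise ConfigError(
                        f"covariate {var!r}/{grp} probabilities sum to "
                        f"{probs.sum():.12f}, not 1"
                    )
        if not 0.0 <= self.distractor_fraction < 1.0:
            raise ConfigError("distractor_fraction must lie in [0, 1)")
        for k, v in self.missing_rates.items():
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"missing rate {k!r}={v} outside [0, 1)")
        # noise parameterization must be solvable
        self.los_model.lognormal_params()
        self.charges_model.lognormal_params()

    def copy(self) -> "SimConfig":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = copy.deepcopy(raw)
        raw["complication_models"] = {
            k: LogisticSpec(**v) for k, v in raw["complication_models"].items()
        }
        raw["mortality_model"] = LogisticSpec(**raw["mortality_model"])
        raw["los_model"] = LinearSpec(**raw["los_model"])
        raw["charges_model"] = LinearSpec(**raw["charges_model"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# term resolution: map a coefficient name onto a column of the covariate frame
# ---------------------------------------------------------------------------

def _term_values(term: str, frame: pd.DataFrame) -> np.ndarray:
    """Indicator/numeric column for a coefficient name.

    Recognized forms: a frame column used as-is (``obese``, ``elective`` ...)
    or ``<var>_<level>`` meaning the indicator ``frame[var] == level``
    (``race_black``, ``income_Q2`` -> ``income_quartile == 'Q2'``).
    """
    if term in frame.columns:
        return frame[term].to_numpy(dtype=float)
    for var in frame.columns:
        prefix = var + "_"
        if term.startswith(prefix):
            return (frame[var] == term[len(prefix):]).to_numpy(dtype=float)
    if term.startswith("income_"):
        return (frame["income_quartile"] == term[len("income_"):]).to_numpy(dtype=float)
    raise ConfigError(f"cannot resolve model term {term!r} against covariates")


def _linear_predictor(spec: LogisticSpec | LinearSpec, frame: pd.DataFrame) -> np.ndarray:
    eta = np.full(len(frame), float(spec.intercept))
    for term, beta in spec.terms.items():
        eta += beta * _term_values(term, frame)
    return eta


# ---------------------------------------------------------------------------
# exact population-average probabilities (calibration + test oracle)
# ---------------------------------------------------------------------------

def _needed_vars(spec: LogisticSpec, tables) -> list[str]:
    vars_: list[str] = []
    for term in spec.terms:
        if term == "obese":
            continue
        if term in tables:
            vars_.append(term)
            continue
        hit = None
        for var in tables:
            if term.startswith(var + "_"):
                hit = var
                break
        if hit is None and term.startswith("income_"):
            hit = "income_quartile"
        if hit is None:
            raise ConfigError(f"term {term!r} not resolvable for calibration")
        vars_.append(hit)
    return sorted(set(vars_))


def _covariate_cells(config: SimConfig, vars_: list[str]) -> pd.DataFrame:
    """Exact joint distribution of (obese, vars_) as a weighted cell table."""
    rows = []
    for obese, grp in ((0, "non_obese"), (1, "obese")):
        w0 = (1 - config.obesity_prevalence) if obese == 0 else config.obesity_prevalence
        levelsets = [list(config.covariate_tables[v][grp].items()) for v in vars_]
        for combo in product(*levelsets) if levelsets else [()]:
            w = w0
            cell = {"obese": obese}
            for v, (lvl, p) in zip(vars_, combo):
                w *= p
                cell[v] = _coerce_level(lvl)
            cell["_w"] = w
            rows.append(cell)
    return pd.DataFrame(rows)


def _coerce_level(lvl):
    # binary tables use "0"/"1" string keys; expose them as ints so that
    # term names like "elective" resolve as numeric columns
    return int(lvl) if lvl in ("0", "1") else lvl


def analytic_prevalence(config: SimConfig, model: str) -> float:
    """Exact population-average probability for one generating logistic model,
    by enumeration of the (obesity x covariate) joint distribution.

    For the mortality model the five mediator flags are integrated out using
    their conditional independence given the covariate cell.
    """
    if model == "mortality":
        return _mortality_prevalence(config, config.mortality_model.intercept)
    spec = config.complication_models[model]
    cells = _covariate_cells(config, _needed_vars(spec, config.covariate_tables))
    eta = _linear_predictor(spec, cells.drop(columns="_w"))
    return float(np.sum(cells["_w"].to_numpy() * expit(eta)))


def _mortality_prevalence(config: SimConfig, intercept: float) -> float:
    mediators = list(config.mortality_model.terms)
    vars_ = sorted({v for m in mediators
                    for v in _needed_vars(config.complication_models[m],
                                          config.covariate_tables)})
    cells = _covariate_cells(config, vars_)
    frame = cells.drop(columns="_w")
    w = cells["_w"].to_numpy()
    pmat = np.column_stack([
        expit(_linear_predictor(config.complication_models[m], frame))
        for m in mediators
    ])                                              # (cells, 5)
    total = 0.0
    betas = np.array([config.mortality_model.terms[m] for m in mediators])
    for flags in product((0, 1), repeat=len(mediators)):
        f = np.array(flags, dtype=float)
        pj = np.prod(np.where(f == 1, pmat, 1.0 - pmat), axis=1)   # P(flags|cell)
        p_death = expit(intercept + float(betas @ f))
        total += float(np.sum(w * pj) * p_death)
    return total


def calibrate_intercepts(config: SimConfig,
                         targets: dict[str, float],
                         tol: float = 1e-10) -> SimConfig:
    """Return a config whose intercepts hit the target population-average
    prevalences exactly (to ``tol``), by monotone 1-D root finding on the
    analytic average probability.

    ``targets`` maps complication names (and optionally ``"mortality"``) to
    proportions in (0, 1).  Raises :class:`ConfigError` when a target is not
    attainable for any finite intercept.
    """
    for name, t in targets.items():
        if not 0.0 < t < 1.0:
            raise ConfigError(f"target prevalence for {name!r} must be in (0,1)")
    out = config.copy()
    lo, hi = -30.0, 30.0

    def solve(fn, name, t):
        if not fn(lo) < t < fn(hi):
            raise ConfigError(f"target {t} for {name!r} unattainable given "
                              "the covariate effects")
        return brentq(lambda c: fn(c) - t, lo, hi, xtol=tol)

    for name, t in targets.items():
        if name == "mortality":
            continue
        spec = out.complication_models[name]

        def mean_p(c, spec=spec):
            cells = _covariate_cells(out, _needed_vars(spec, out.covariate_tables))
            eta = _linear_predictor(
                LogisticSpec(c, spec.terms), cells.drop(columns="_w"))
            return float(np.sum(cells["_w"].to_numpy() * expit(eta)))

        spec.intercept = float(solve(mean_p, name, t))

    if "mortality" in targets:
        out.mortality_model.intercept = float(solve(
            lambda c: _mortality_prevalence(out, c), "mortality",
            targets["mortality"]))
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    obese = (rng.random(n) < config.obesity_prevalence).astype(int)
    frame = pd.DataFrame({"obese": obese})
    for var, groups in config.covariate_tables.items():
        out = np.empty(n, dtype=object)
        for gidx, grp in ((0, "non_obese"), (1, "obese")):
            mask = obese == gidx
            levels = list(groups[grp])
            probs = np.array([groups[grp][l] for l in levels], dtype=float)
            probs = probs / probs.sum()
            out[mask] = rng.choice(np.array(levels, dtype=object),
                                   size=int(mask.sum()), p=probs)
        frame[var] = [_coerce_level(v) for v in out]
    # exact age in years, uniform within the sampled band
    lo = frame["age_group"].map(lambda b: AGE_BANDS[b][0]).to_numpy()
    hi = frame["age_group"].map(lambda b: AGE_BANDS[b][1]).to_numpy()
    frame["age_years"] = rng.integers(lo, hi + 1)
    return frame


def simulate_frame(config: SimConfig) -> pd.DataFrame:
    """Draw the full synthetic cohort as a flat truth table (one row per
    admission, flags as 0/1 columns).  :func:`generate_population` encodes
    this frame into ICD-9-coded :class:`InpatientRecord` objects."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.n_patients == 0:
        return pd.DataFrame()
    frame = _sample_covariates(config, rng)
    n = len(frame)

    for name, spec in config.complication_models.items():
        p = expit(_linear_predictor(spec, frame))
        frame[name] = (rng.random(n) < p).astype(int)

    p_death = expit(_linear_predictor(config.mortality_model, frame))
    frame["died"] = (rng.random(n) < p_death).astype(int)

    for col, spec in (("los_days", config.los_model),
                      ("total_charges", config.charges_model)):
        mu, sigma = spec.lognormal_params()
        noise = rng.lognormal(mu, sigma, size=n) - spec.noise_mean
        frame[col] = _linear_predictor(spec, frame) + noise

    for col in ("died", "los_days", "total_charges"):
        rate = config.missing_rates.get(col, 0.0)
        frame[f"missing_{col}"] = ((rng.random(n) < rate).astype(int)
                                   if rate > 0 else 0)

    if config.distractor_fraction > 0:
        is_distractor = rng.random(n) < config.distractor_fraction
        kind = rng.integers(0, 3, size=n)      # 0: other cancer, 1: no surgery, 2: age<20
        frame["distractor_kind"] = np.where(is_distractor, kind, -1)
    else:
        frame["distractor_kind"] = -1
    return frame


def records_from_frame(frame: pd.DataFrame, rng: np.random.Generator) -> list[InpatientRecord]:
    """Encode a truth frame into ICD-9-coded admission records."""
    if frame.empty:
        return []
    n = len(frame)
    crc = rng.choice(_CRC_CODES, size=n)
    met = rng.choice(_MET_CODES, size=n)
    surg = rng.choice(_SURG_CODES, size=n)
    records = []
    comp_names = [c for c in _COMPLICATION_CODE if c in frame.columns]
    for i, row in enumerate(frame.itertuples(index=False)):
        r = row._asdict()
        kind = r.get("distractor_kind", -1)
        dx = [str(crc[i])]
        if kind == 0:
            dx.append("162.9")          # a lung-cancer code: excluded range
        if r["metastasis"]:
            dx.append(str(met[i]))
        if r["obese"]:
            dx.append("278.00")
        for cmb, code in _COMORBIDITY_CODE.items():
            if r.get(cmb):
                dx.append(code)
        for comp in comp_names:
            if r[comp]:
                dx.append(_COMPLICATION_CODE[comp])
        proc = [] if kind == 1 else [str(surg[i])]
        age = 18 if kind == 2 else int(r["age_years"])
        records.append(InpatientRecord(
            record_id=f"R{i:07d}",
            dx_codes=dx,
            proc_codes=proc,
            age_years=age,
            sex=r["sex"],
            race=r["race"],
            income_quartile=r["income_quartile"],
            elective=bool(r["elective"]),
            bed_size=r["bed_size"],
            urban=bool(r["urban"]),
            teaching=bool(r["teaching"]),
            died=None if r["missing_died"] else bool(r["died"]),
            los_days=None if r["missing_los_days"] else float(max(r["los_days"], 0.0)),
            total_charges=None if r["missing_total_charges"]
                          else float(max(r["total_charges"], 0.0)),
        ))
    return records


def generate_population(config: SimConfig) -> list[InpatientRecord]:
    """Generate ``config.n_patients`` ICD-9-coded admission records.

    Deterministic: identical (config, seed) pairs give identical output.
    Configuration errors are raised before any sampling.
    """
    config.validate()
    frame = simulate_frame(config)
    # a child stream keeps code-assignment draws independent of the frame's
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    return records_from_frame(frame, rng)


# ---------------------------------------------------------------------------
# defaults: the published-study conditions
# ---------------------------------------------------------------------------

#: target population prevalences for calibration: the five mediators use the
#: published dependent-variable means, death uses the published mortality
#: model mean; the eight remaining endpoints (not modelled in the source
#: tables) get claims-realistic rates with no obesity effect.
DEFAULT_TARGETS: dict[str, float] = {
    "infection": 0.046, "shock": 0.003, "bleeding": 0.021,
    "wound_disruption": 0.012, "digestive": 0.120,
    "nonhealing_wound": 0.005, "nervous": 0.004, "cardiac": 0.025,
    "phlebitis": 0.003, "respiratory": 0.035, "urinary": 0.030,
    "vascular": 0.002, "unspecified": 0.015,
    "mortality": 0.022,
}


def _normalized_tables() -> dict:
    tables = {}
    for var, groups in published.COVARIATE_TABLES.items():
        tables[var] = {}
        for grp, counts in groups.items():
            total = float(sum(counts.values()))
            tables[var][grp] = {lvl: c / total for lvl, c in counts.items()}
    return tables


def default_config(n_patients: int,
                   seed: int = 0,
                   distractor_fraction: float = 0.0,
                   calibrate: bool = True) -> SimConfig:
    """Generating configuration at the published study conditions.

    Covariate distributions come from the published cohort-characteristics
    counts (conditional on obesity); complication and mortality models use
    the published logistic coefficients; LOS/charges use the published OLS
    coefficients with mean-zero log-normal noise anchored to the observed
    dispersion (SD ~8 days, ~$80k).  Intercepts are calibrated so that each
    model's population-average prevalence hits :data:`DEFAULT_TARGETS`.
    """
    comp_models = {
        name: LogisticSpec(intercept=m["intercept"], terms=dict(m["terms"]))
        for name, m in published.COMPLICATION_MODELS.items()
    }
    for name, t in DEFAULT_TARGETS.items():
        if name in ("mortality",) or name in comp_models:
            continue
        comp_models[name] = LogisticSpec(intercept=float(logit(t)), terms={})
    n_total = float(published.TOTAL_N)
    config = SimConfig(
        n_patients=n_patients,
        obesity_prevalence=published.OBESITY_PREVALENCE,
        covariate_tables=_normalized_tables(),
        complication_models=comp_models,
        mortality_model=LogisticSpec(
            intercept=published.MORTALITY_MODEL["intercept"],
            terms=dict(published.MORTALITY_MODEL["terms"])),
        los_model=LinearSpec(
            intercept=published.LOS_MODEL["intercept"],
            terms=dict(published.LOS_MODEL["terms"]),
            noise_mean=8.0, noise_sd=8.0),
        charges_model=LinearSpec(
            intercept=published.CHARGES_MODEL["intercept"],
            terms=dict(published.CHARGES_MODEL["terms"]),
            noise_mean=50_000.0, noise_sd=80_000.0),
        missing_rates={
            "died": published.MISSING_COUNTS["died"] / n_total,
            "los_days": published.MISSING_COUNTS["los_days"] / n_total,
            "total_charges": published.MISSING_COUNTS["total_charges"] / n_total,
        },
        distractor_fraction=distractor_fraction,
        seed=seed,
    )
    if calibrate:
        config = calibrate_intercepts(config, DEFAULT_TARGETS)
    return config
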