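"""End-to-end pipeline: simulate/ingest -> extract -> match -> describe ->
fit -> paths, with publication-shaped artifacts at every stage boundary.

Every artifact is CSV or JSON; a run log records seeds, row counts per
stage and library versions, so a bundle is reproducible byte-for-byte from
its configuration.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import published
from .codes import CodeBook, DEFAULT_CODEBOOK
from .cohort import AttritionLog, extract_cohort
from .descriptives import (characteristics_table, comparisons_frame,
                           outcomes_table)
from .effects import MarginalEffect, PathSummary, build_paths, marginal_effect
from .glm import (ConvergenceError, LogisticFit, OLSFit, SeparationError,
                  fit_logistic, fit_ols, select_mediators)
from .matching import MatchedCohort, match_1to4, matched_rows
from .records import read_records, write_records
from .simulate import SimConfig, default_config, generate_population


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and row-count context."""

    def __init__(self, stage: str, n_rows: int, cause: BaseException):
        self.stage, self.n_rows, self.cause = stage, n_rows, cause
        super().__init__(f"stage {stage!r} failed with {n_rows} rows: {cause}")


@dataclass
class PipelineConfig:
    """Exactly one of ``input_path`` / ``simulate`` drives the pipeline."""
    input_path: str | None = None
    simulate: SimConfig | None = None
    codebook: CodeBook = field(default_factory=lambda: DEFAULT_CODEBOOK)
    match_key: tuple[str, ...] = ("age_group", "sex", "metastasis")
    match_ratio: int = 4
    match_seed: int = 0
    adjustment: tuple[str, ...] = published.DEFAULT_ADJUSTMENT
    alpha: float = 0.05
    candidates: tuple[str, ...] = published.COMPLICATIONS
    outdir: str | None = None
    write_records_csv: bool = False

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of input_path / simulate must be given")
        if self.simulate is not None:
            self.simulate.validate()


@dataclass
class ResultBundle:
    cohort: pd.DataFrame
    attrition: AttritionLog
    matched: MatchedCohort
    analysis_rows: pd.DataFrame
    characteristics: list
    outcomes: list
    complication_fits: dict[str, LogisticFit]
    skipped_models: dict[str, str]
    mediators: list[str]
    mortality_fit: LogisticFit
    los_fit: OLSFit
    charges_fit: OLSFit
    paths: PathSummary
    run_log: dict


def _strip_c(name: str) -> str:
    return name[2:] if name.startswith("c_") else name


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the full analysis; optionally write a result bundle to
    ``config.outdir``.  Deterministic given the configuration."""
    config.validate()
    log: dict = {"stages": {}, "versions": _versions()}

    # -- ingest / simulate ---------------------------------------------------
    try:
        if config.simulate is not None:
            records = generate_population(config.simulate)
            log["seed"] = config.simulate.seed
        else:
            records = read_records(config.input_path)
    except Exception as exc:
        raise StageError("ingest", 0, exc) from exc
    log["stages"]["ingest"] = len(records)

    # -- extract -------------------------------------------------------------
    try:
        cohort, attrition = extract_cohort(records, config.codebook)
    except Exception as exc:
        raise StageError("extract", len(records), exc) from exc
    log["stages"]["extract"] = len(cohort)

    # -- match ---------------------------------------------------------------
    try:
        matched = match_1to4(cohort, key=config.match_key,
                             ratio=config.match_ratio, seed=config.match_seed)
        rows = matched_rows(cohort, matched)
    except Exception as exc:
        raise StageError("match", len(cohort), exc) from exc
    log["stages"]["match"] = len(rows)
    log["match"] = {"cases": len(matched.pairs),
                    "unmatched": len(matched.unmatched),
                    "seed": config.match_seed}

    # -- descriptives --------------------------------------------------------
    try:
        characteristics = characteristics_table(rows)
        outcomes = outcomes_table(rows)
    except Exception as exc:
        raise StageError("describe", len(rows), exc) from exc

    # -- regression layer ----------------------------------------------------
    fits: dict[str, LogisticFit] = {}
    skipped: dict[str, str] = {}
    predictors = ["obese", *config.adjustment]
    for comp in config.candidates:
        try:
            fits[comp] = fit_logistic(rows, f"c_{comp}", predictors)
        except (ValueError, SeparationError, ConvergenceError) as exc:
            skipped[comp] = str(exc)
    if not fits:
        raise StageError("fit", len(rows),
                         RuntimeError("no complication model could be fitted"))

    mediators = select_mediators(fits, term="obese", alpha=config.alpha)
    if not mediators:
        raise StageError("fit", len(rows), RuntimeError(
            "no complication significantly related to the exposure"))
    med_cols = [f"c_{m}" for m in mediators]

    try:
        mortality_fit = fit_logistic(rows, "died", med_cols)
        los_fit = fit_ols(rows, "los_days", med_cols)
        charges_fit = fit_ols(rows, "total_charges", med_cols)
    except (ValueError, SeparationError, ConvergenceError) as exc:
        raise StageError("fit", len(rows), exc) from exc
    log["stages"]["fit"] = {
        "complication_models": len(fits), "skipped": skipped,
        "mediators": mediators,
        "n_mortality": mortality_fit.n_used,
        "n_los": los_fit.n_used, "n_charges": charges_fit.n_used,
    }

    # -- path decomposition --------------------------------------------------
    try:
        exposure_effects = {
            m: marginal_effect(fits[m].terms["obese"].beta,
                               fits[m].dependent_mean, m)
            for m in mediators
        }
        mortality_effects = {
            m: marginal_effect(mortality_fit.terms[f"c_{m}"].beta,
                               mortality_fit.dependent_mean, m)
            for m in mediators
        }
        los_r = _rename_terms(los_fit)
        chg_r = _rename_terms(charges_fit)
        paths = build_paths(exposure_effects, mortality_effects, los_r, chg_r)
    except Exception as exc:
        raise StageError("paths", len(rows), exc) from exc

    bundle = ResultBundle(
        cohort=cohort, attrition=attrition, matched=matched,
        analysis_rows=rows, characteristics=characteristics,
        outcomes=outcomes, complication_fits=fits, skipped_models=skipped,
        mediators=mediators, mortality_fit=mortality_fit, los_fit=los_fit,
        charges_fit=charges_fit, paths=paths, run_log=log)

    if config.outdir is not None:
        write_bundle(bundle, config, Path(config.outdir))
    return bundle


def _rename_terms(fit: OLSFit) -> OLSFit:
    return OLSFit(outcome=fit.outcome,
                  terms={_strip_c(k): v for k, v in fit.terms.items()},
                  n_used=fit.n_used, r2=fit.r2, adj_r2=fit.adj_r2)


def _versions() -> dict:
    import scipy
    import statsmodels
    return {"python": platform.python_version(), "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__}


def write_bundle(bundle: ResultBundle, config: PipelineConfig, outdir: Path) -> None:
    """Serialize every table artifact of a run (CSV/JSON only)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bundle.attrition.to_json(outdir / "attrition.json")
    bundle.cohort.to_csv(outdir / "cohort.csv", index=False)
    bundle.matched.to_dataframe().to_csv(outdir / "matched.csv", index=False)
    comparisons_frame(bundle.characteristics).to_csv(
        outdir / "table1_characteristics.csv", index=False)
    comparisons_frame(bundle.outcomes).to_csv(
        outdir / "table2_outcomes.csv", index=False)

    t3 = []
    for comp, fit in bundle.complication_fits.items():
        frame = fit.summary_frame()
        frame.insert(0, "model", comp)
        frame["dpdx"] = [marginal_effect(b, fit.dependent_mean).value
                         for b in frame["beta"]]
        frame["dependent_mean"] = fit.dependent_mean
        frame["n_events"] = fit.n_events
        frame["minus2_log_L"] = fit.minus2_log_likelihood
        frame["likelihood_ratio"] = fit.likelihood_ratio
        frame["score_chi2"] = fit.score_chi2
        t3.append(frame)
    pd.concat(t3, ignore_index=True).to_csv(
        outdir / "table3_complication_models.csv", index=False)

    mf = bundle.mortality_fit
    t4 = mf.summary_frame()
    t4["dpdx"] = [marginal_effect(b, mf.dependent_mean).value
                  for b in t4["beta"]]
    t4["dependent_mean"] = mf.dependent_mean
    t4["n_events"] = mf.n_events
    t4.to_csv(outdir / "table4_mortality_model.csv", index=False)

    t5 = []
    for fit in (bundle.los_fit, bundle.charges_fit):
        frame = fit.summary_frame()
        frame.insert(0, "outcome", fit.outcome)
        frame["r2"] = fit.r2
        frame["adj_r2"] = fit.adj_r2
        frame["n_used"] = fit.n_used
        t5.append(frame)
    pd.concat(t5, ignore_index=True).to_csv(
        outdir / "table5_ols_models.csv", index=False)

    bundle.paths.to_json(outdir / "paths.json")
    with open(outdir / "path_diagram.json", "w") as fh:
        json.dump(bundle.paths.edge_list(), fh, indent=2)
    with open(outdir / "figure2_paths.txt", "w") as fh:
        fh.write(bundle.paths.format_table() + "\n")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(bundle.run_log, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# replay: rebuild the path diagram from published coefficients
# ---------------------------------------------------------------------------

def run_replay(coefficients_path: str | None = None) -> PathSummary:
    """Replay mode: path decomposition from a coefficient file (JSON with
    ``table3``/``table4``/``table5`` blocks) or, by default, the packaged
    published estimates."""
    from .effects import from_printed_tables
    if coefficients_path is None:
        t3, t4, t5 = published.replay_tables()
    else:
        with open(coefficients_path) as fh:
            raw = json.load(fh)
        t3, t4, t5 = raw["table3"], raw["table4"], raw["table5"]
    return from_printed_tables(t3, t4, t5)
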