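"""Generator behaviour: determinism, calibration, and agreement of realized
rates with the exact analytic population-average probabilities."""

import math

import numpy as np
import pytest

from crcpath.cohort import extract_cohort
from crcpath.records import write_records
from crcpath.simulate import (ConfigError, DEFAULT_TARGETS, LogisticSpec,
                              analytic_prevalence, calibrate_intercepts,
                              default_config, generate_population,
                              simulate_frame)


def test_zero_patients_gives_empty_collection():
    cfg = default_config(100, seed=0, calibrate=False)
    cfg.n_patients = 0
    assert generate_population(cfg) == []


def test_config_errors_raised_before_sampling():
    cfg = default_config(100, seed=0, calibrate=False)
    cfg.n_patients = -5
    with pytest.raises(ConfigError, match="n_patients"):
        generate_population(cfg)
    cfg = default_config(100, seed=0, calibrate=False)
    cfg.covariate_tables["sex"]["obese"] = {"male": 0.7, "female": 0.4}
    with pytest.raises(ConfigError, match="sum to"):
        generate_population(cfg)
    cfg = default_config(100, seed=0, calibrate=False)
    cfg.missing_rates["died"] = 1.5
    with pytest.raises(ConfigError, match="missing rate"):
        generate_population(cfg)


def test_same_seed_same_config_byte_identical(tmp_path):
    cfg = default_config(2_000, seed=42)
    for name in ("a.csv", "b.csv"):
        write_records(generate_population(cfg), tmp_path / name)
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


class TestCalibration:
    def test_all_betas_zero_target_half_gives_zero_intercept(self):
        cfg = default_config(10, seed=0, calibrate=False)
        cfg.complication_models = {"only": LogisticSpec(intercept=2.0, terms={})}
        cfg.mortality_model = LogisticSpec(intercept=-3.0, terms={})
        out = calibrate_intercepts(cfg, {"only": 0.5})
        assert abs(out.complication_models["only"].intercept) < 1e-9

    def test_all_betas_zero_closed_form_logit(self):
        cfg = default_config(10, seed=0, calibrate=False)
        cfg.complication_models = {"only": LogisticSpec(intercept=0.0, terms={})}
        cfg.mortality_model = LogisticSpec(intercept=-3.0, terms={})
        out = calibrate_intercepts(cfg, {"only": 0.046})
        assert out.complication_models["only"].intercept == pytest.approx(
            math.log(0.046 / 0.954), abs=1e-8)

    def test_published_infection_model_hits_target_mean(self):
        cfg = default_config(10, seed=0)   # calibrated default
        assert analytic_prevalence(cfg, "infection") == pytest.approx(0.046, abs=1e-8)
        assert analytic_prevalence(cfg, "mortality") == pytest.approx(0.022, abs=1e-8)

    def test_unattainable_target_reported(self):
        cfg = default_config(10, seed=0, calibrate=False)
        with pytest.raises(ConfigError, match="target"):
            calibrate_intercepts(cfg, {"infection": 1.2})


def test_realized_prevalence_matches_analytic_average():
    """Realized complication rates agree with exact enumeration of the
    logistic over the covariate distribution, within 3 binomial SEs."""
    n = 60_000
    cfg = default_config(n, seed=5)
    frame = simulate_frame(cfg)
    for name in ("infection", "bleeding", "digestive"):
        p = analytic_prevalence(cfg, name)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frame[name].mean() - p) < 3 * se
    p = analytic_prevalence(cfg, "mortality")
    se = math.sqrt(p * (1 - p) / n)
    assert abs(frame["died"].mean() - p) < 3 * se


def test_null_obesity_beta_gives_no_group_gap():
    """With the obesity coefficient zeroed everywhere -- and the covariate
    distributions equalized between groups, removing indirect channels --
    obese vs non-obese complication prevalences differ by sampling error
    only (binomial SE oracle)."""
    n = 80_000
    cfg = default_config(n, seed=9, calibrate=False)
    for spec in cfg.complication_models.values():
        spec.terms.pop("obese", None)
    for var in cfg.covariate_tables:
        cfg.covariate_tables[var]["obese"] = dict(
            cfg.covariate_tables[var]["non_obese"])
    frame = simulate_frame(cfg)
    obese = frame[frame["obese"] == 1]
    non = frame[frame["obese"] == 0]
    # five simultaneous binomial checks: use a family-wise 4-SE bound
    # (per-comparison 3 SE would fail a true null ~1.3% of the time here)
    for name in ("infection", "shock", "bleeding", "wound_disruption", "digestive"):
        p = frame[name].mean()
        se = math.sqrt(p * (1 - p) * (1 / len(obese) + 1 / len(non)))
        gap = obese[name].mean() - non[name].mean()
        assert abs(gap) < 4 * se, name


def test_larger_obesity_beta_strictly_widens_analytic_gap():
    """Effect direction: raising the obesity coefficient raises the obese-
    group analytic prevalence (exact enumeration, no sampling)."""
    def obese_prev(beta):
        cfg = default_config(10, seed=0, calibrate=False)
        cfg.complication_models["infection"].terms["obese"] = beta
        cfg.obesity_prevalence = 1.0 - 1e-12   # condition on the obese group
        return analytic_prevalence(cfg, "infection")

    prevs = [obese_prev(b) for b in (0.0, 0.43, 0.9, 1.5)]
    assert all(a < b for a, b in zip(prevs, prevs[1:]))


def test_missingness_rates_and_outcome_positivity():
    cfg = default_config(40_000, seed=3)
    frame = simulate_frame(cfg)
    assert frame["missing_total_charges"].mean() == pytest.approx(
        cfg.missing_rates["total_charges"], abs=0.005)
    assert (frame["los_days"] > 0).all()
    assert (frame["total_charges"] > 0).all()
    # noise anchors: SD near the configured scales
    assert 5 < frame["los_days"].std() < 12
    assert 50_000 < frame["total_charges"].std() < 120_000


def test_group_conditional_covariates_reproduce_diabetes_association():
    cfg = default_config(40_000, seed=4)
    frame = simulate_frame(cfg)
    obese = frame[frame["obese"] == 1]
    non = frame[frame["obese"] == 0]
    assert obese["diabetes"].mean() == pytest.approx(0.4072, abs=0.03)
    assert non["diabetes"].mean() == pytest.approx(0.1872, abs=0.02)


def test_distractors_fail_exactly_one_rule():
    cfg = default_config(5_000, seed=6, distractor_fraction=0.25)
    records = generate_population(cfg)
    rows, log = extract_cohort(records)
    n_removed = sum(log.removed.values())
    assert n_removed > 0.2 * len(records)
    assert log.n_kept + n_removed == len(records)
    for rule in ("age_under_20", "no_crc_dx", "no_surgery_proc", "other_cancer_dx"):
        assert log.removed[rule] >= 0
    # the three injected violation kinds all occur
    assert log.removed["age_under_20"] > 0
    assert log.removed["no_surgery_proc"] > 0
    assert log.removed["other_cancer_dx"] > 0
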