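"""Reference estimates from the motivating NIS-based analysis (2004-2014,
surgical colorectal-cancer admissions, obesity exposure).

These numbers serve two distinct roles:

1. **Simulation ground truth** -- the default :class:`crcpath.simulate.SimConfig`
   uses the logistic / OLS coefficients below as generating parameters, and the
   group-conditional covariate tables as sampling distributions, so that the
   synthetic cohort has the causal structure the analysis assumes.
2. **Replay inputs** -- :func:`crcpath.effects.from_printed_tables` can rebuild
   the exposure -> complication -> outcome path decomposition directly from
   these published coefficients, without any microdata.

The licensed NIS microdata are not redistributable; nothing here is patient
level.  All dictionaries are plain data and safe to copy/modify.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Cohort-level counts (unmatched / matched)
# ---------------------------------------------------------------------------

TOTAL_N = 107_067          # admissions meeting inclusion criteria
OBESE_N = 8_412            # obesity dx (278.0) present, unmatched
NONOBESE_N = 98_655
MATCHED_OBESE_N = 8_411    # one case had no feasible 1:4 stratum
MATCHED_NONOBESE_N = 33_644
MATCHED_COHORT_N = 42_055  # 8,411 cases + 33,644 controls

#: canonical mediator order used throughout the package
MEDIATORS = ("infection", "shock", "bleeding", "wound_disruption", "digestive")

#: all thirteen postoperative-complication endpoints, canonical order
COMPLICATIONS = (
    "infection",            # 998.5
    "shock",                # 998.0
    "bleeding",             # 998.1
    "wound_disruption",     # 998.3
    "nonhealing_wound",     # 998.83
    "nervous",              # 997.0
    "cardiac",              # 997.1
    "phlebitis",            # 997.2
    "respiratory",          # 997.3
    "digestive",            # 997.4
    "urinary",              # 997.5
    "vascular",             # 997.7
    "unspecified",          # 998.9
)

# ---------------------------------------------------------------------------
# Covariate distributions, conditional on obesity (unmatched cohort counts)
# ---------------------------------------------------------------------------
# Counts are used rather than the printed (rounded) percentages; each block
# normalizes to 1.  Sampling covariates conditionally on the exposure
# reproduces the published group differences (notably diabetes: 40.72% obese
# vs 18.72% non-obese) without a full dependence model.

COVARIATE_TABLES: dict[str, dict[str, dict[str, float]]] = {
    "sex": {
        "non_obese": {"male": 49_432, "female": 49_223},
        "obese": {"male": 3_944, "female": 4_468},
    },
    "age_group": {
        "non_obese": {"20-44": 4_800, "45-59": 21_048, "60-74": 34_979, "75+": 37_828},
        "obese": {"20-44": 438, "45-59": 2_479, "60-74": 3_779, "75+": 1_716},
    },
    "race": {
        "non_obese": {
            "white": 76_725, "black": 9_634, "hispanic": 6_460,
            "asian_pi": 3_018, "other": 2_818,
        },
        "obese": {
            "white": 6_448, "black": 1_039, "hispanic": 601,
            "asian_pi": 88, "other": 236,
        },
    },
    "income_quartile": {
        "non_obese": {"Q1": 24_532, "Q2": 24_934, "Q3": 24_257, "Q4": 24_932},
        "obese": {"Q1": 2_225, "Q2": 2_124, "Q3": 2_155, "Q4": 1_908},
    },
    "elective": {
        "non_obese": {"1": 64_127, "0": 34_528},
        "obese": {"1": 5_935, "0": 2_477},
    },
    "metastasis": {
        "non_obese": {"1": 34_884, "0": 63_771},
        "obese": {"1": 2_581, "0": 5_831},
    },
    "alcohol_abuse": {
        "non_obese": {"1": 1_896, "0": 96_759},
        "obese": {"1": 145, "0": 8_267},
    },
    "diabetes": {
        "non_obese": {"1": 18_473, "0": 80_182},
        "obese": {"1": 3_425, "0": 4_987},
    },
    "liver_disease": {
        "non_obese": {"1": 1_809, "0": 96_846},
        "obese": {"1": 249, "0": 8_163},
    },
    "bed_size": {
        "non_obese": {"small": 12_136, "medium": 24_109, "large": 62_410},
        "obese": {"small": 944, "medium": 2_121, "large": 5_347},
    },
    "urban": {
        "non_obese": {"1": 87_521, "0": 11_134},
        "obese": {"1": 7_612, "0": 800},
    },
    "teaching": {
        "non_obese": {"1": 43_760, "0": 54_895},
        "obese": {"1": 3_937, "0": 4_475},
    },
}

OBESITY_PREVALENCE = OBESE_N / TOTAL_N  # 0.0786

# ---------------------------------------------------------------------------
# Logistic models: complication ~ obesity + adjustment set (matched cohort)
# ---------------------------------------------------------------------------
# Term naming follows the design-matrix columns produced by crcpath.glm:
# reference levels are white race, Q1 income, non-elective, rural,
# non-teaching.  "dpdx" is the published absolute marginal effect
# beta * P * (1 - P) for the obesity term, at P = dependent-variable mean.

COMPLICATION_MODELS: dict[str, dict] = {
    "infection": {
        "intercept": -3.08,
        "terms": {
            "obese": 0.43,
            "race_other": -0.02, "race_asian_pi": 0.23,
            "race_hispanic": 0.004, "race_black": 0.02,
            "income_Q4": 0.06, "income_Q3": 0.05, "income_Q2": 0.01,
            "elective": -0.44, "urban": 0.04, "teaching": 0.33,
        },
        "or_obese": (1.54, 1.39, 1.71),
        "dpdx_obese": 0.0190,
        "dependent_mean": 0.046,
        "n_events": 1_945,
        "n_used": MATCHED_COHORT_N,
    },
    "shock": {
        "intercept": -6.80,
        "terms": {
            "obese": 0.72,
            "race_other": 0.36, "race_asian_pi": 0.64,
            "race_hispanic": 0.17, "race_black": -0.12,
            "income_Q4": 0.59, "income_Q3": 0.48, "income_Q2": 0.30,
            "elective": -0.65, "urban": 1.06, "teaching": -0.10,
        },
        "or_obese": (2.05, 1.45, 2.91),
        "dpdx_obese": 0.0025,
        "dependent_mean": 0.003,
        "n_events": 147,
        "n_used": MATCHED_COHORT_N,
    },
    "bleeding": {
        "intercept": -3.89,
        "terms": {
            "obese": 0.24,
            "race_other": 0.15, "race_asian_pi": -0.16,
            "race_hispanic": 0.02, "race_black": -0.04,
            "income_Q4": -0.02, "income_Q3": 0.11, "income_Q2": 0.09,
            "elective": -0.06, "urban": -0.05, "teaching": 0.08,
        },
        "or_obese": (1.28, 1.09, 1.49),
        "dpdx_obese": 0.0050,
        "dependent_mean": 0.021,
        "n_events": 886,
        "n_used": MATCHED_COHORT_N,
    },
    "wound_disruption": {
        "intercept": -4.07,
        "terms": {
            "obese": 0.51,
            "race_other": -0.47, "race_asian_pi": 0.003,
            "race_hispanic": 0.08, "race_black": -0.10,
            "income_Q4": -0.28, "income_Q3": -0.07, "income_Q2": -0.02,
            "elective": -0.61, "urban": -0.24, "teaching": 0.46,
        },
        "or_obese": (1.66, 1.37, 2.02),
        "dpdx_obese": 0.0060,
        "dependent_mean": 0.012,
        "n_events": 505,
        "n_used": MATCHED_COHORT_N,
    },
    "digestive": {
        "intercept": -1.98,
        "terms": {
            "obese": 0.13,
            "race_other": -0.10, "race_asian_pi": -0.10,
            "race_hispanic": -0.18, "race_black": 0.10,
            "income_Q4": -0.04, "income_Q3": 0.01, "income_Q2": -0.02,
            "elective": -0.17, "urban": 0.15, "teaching": -0.09,
        },
        "or_obese": (1.14, 1.06, 1.22),
        "dpdx_obese": 0.0135,
        "dependent_mean": 0.120,
        "n_events": 5_063,
        "n_used": MATCHED_COHORT_N,
    },
}

#: default adjustment covariates for the complication models (the set the
#: published tables actually display).
DEFAULT_ADJUSTMENT = ("race", "income_quartile", "elective", "urban", "teaching")

# ---------------------------------------------------------------------------
# Logistic model: in-hospital death ~ five complications (matched cohort)
# ---------------------------------------------------------------------------

MORTALITY_MODEL: dict = {
    "intercept": -3.97,
    "terms": {
        "infection": 0.83,
        "shock": 2.45,
        "bleeding": 0.57,
        "wound_disruption": 0.62,
        "digestive": 0.22,
    },
    "dpdx": {
        "infection": 0.0176,
        "shock": 0.0521,
        "bleeding": 0.0121,
        "wound_disruption": 0.0132,
        "digestive": 0.0046,
    },
    "dependent_mean": 0.022,
    "n_events": 912,
    "n_used": 42_046,   # nine matched rows missing the death flag
}

# ---------------------------------------------------------------------------
# OLS models: LOS (days) and total charges (USD) ~ five complications
# ---------------------------------------------------------------------------

LOS_MODEL: dict = {
    "intercept": 8.08,
    "terms": {
        "infection": 8.42,
        "shock": 8.68,
        "bleeding": 3.15,
        "wound_disruption": 11.09,
        "digestive": 3.94,
    },
    "ci": {
        "infection": (8.07, 8.77),
        "shock": (7.46, 9.89),
        "bleeding": (2.65, 3.65),
        "wound_disruption": (10.43, 11.76),
        "digestive": (3.72, 4.16),
    },
    "n_used": 42_054,
    "r2": 0.1332,
    "adj_r2": 0.1331,
}

CHARGES_MODEL: dict = {
    "intercept": 54_795.0,
    "terms": {
        "infection": 62_169.0,
        "shock": 85_247.0,
        "bleeding": 30_770.0,
        "wound_disruption": 86_760.0,
        "digestive": 23_378.0,
    },
    "ci": {
        "infection": (58_887.0, 65_451.0),
        "shock": (73_746.0, 96_748.0),
        "bleeding": (26_075.0, 35_464.0),
        "wound_disruption": (80_563.0, 92_958.0),
        "digestive": (21_302.0, 25_455.0),
    },
    "n_used": 40_421,
    "r2": 0.0886,
    "adj_r2": 0.0885,
}

# ---------------------------------------------------------------------------
# Outcome summaries (matched), per-outcome missing counts, noise anchors
# ---------------------------------------------------------------------------

MATCHED_OUTCOMES = {
    "mortality": {"non_obese": (764, 33_644), "obese": (148, 8_411)},
    "infection": {"non_obese": (1_419, 33_644), "obese": (526, 8_411)},
}

#: per-outcome missing counts over the unmatched cohort of 107,067
MISSING_COUNTS = {"died": 61, "los_days": 2, "total_charges": 3_154}

#: observed LOS/charges dispersion (matched obese column) used to anchor the
#: generator's noise scales: SD ~= 8 days, ~= $80k.
LOS_SD = 7.93
CHARGES_SD = 82_483.0


def replay_tables() -> tuple[dict, dict, dict]:
    """Published coefficients packaged for :func:`effects.from_printed_tables`.

    Returns the three per-mediator tables (exposure->complication,
    complication->death, complication->LOS/charges) with the printed
    marginal effects attached, so replay reproduces the published path
    diagram without refitting anything.
    """
    t3 = {
        m: {"beta": COMPLICATION_MODELS[m]["terms"]["obese"],
            "p": COMPLICATION_MODELS[m]["dependent_mean"],
            "dpdx": COMPLICATION_MODELS[m]["dpdx_obese"]}
        for m in MEDIATORS
    }
    t4 = {
        m: {"beta": MORTALITY_MODEL["terms"][m],
            "p": MORTALITY_MODEL["n_events"] / MORTALITY_MODEL["n_used"],
            "dpdx": MORTALITY_MODEL["dpdx"][m]}
        for m in MEDIATORS
    }
    t5 = {
        m: {"los": LOS_MODEL["terms"][m], "charges": CHARGES_MODEL["terms"][m]}
        for m in MEDIATORS
    }
    return t3, t4, t5
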