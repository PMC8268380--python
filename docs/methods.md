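# Methods

## Scope and model

`crcpath` implements a mediation-style path analysis on hospital-admission
records: an exposure (obesity, ICD-9-CM 278.0) influences three outcomes
(in-hospital death, length of stay, total charges) through intermediate
postoperative complications. The estimand is the *total indirect effect*
Σᵢ aᵢbᵢ over mediators i, where every edge is an **absolute** effect:

- aᵢ = βᵢ·Pᵢ·(1−Pᵢ): the marginal probability change of complication i per
  unit of the exposure, from a logistic model
  `complication ~ obesity + covariates`, evaluated at the complication's
  dependent-variable mean Pᵢ in the model's estimation sample;
- bᵢ: for death, the analogous marginal probability β·P·(1−P) from
  `death ~ mediators`; for LOS (days) and charges (US dollars), the OLS
  coefficient of mediator i.

The β·P·(1−P) form is the derivative of the logistic mean evaluated where
the predicted probability equals P; we deliberately evaluate it at the
sample prevalence rather than averaging per-observation derivatives, which
reproduces the convention of the motivating analysis (0.43 × 0.046 × 0.954
≈ 0.019 for obesity → infection). Unlike odds ratios, absolute effects
multiply along a path and add across paths; totals include only the
mediated paths (no direct exposure → outcome edge).

This is a path-coefficient product decomposition, not a counterfactual
mediation analysis: no natural direct/indirect effects, no
exposure-mediator interactions, and no uncertainty intervals on the
products (none are defined in the convention followed; a patient-level
bootstrap could be layered on top by resampling and re-running
`run_pipeline`).

## Cohort and codes

Inclusion: age ≥ 20, a CRC diagnosis (roots 153/154), a qualifying
resection procedure (45.7x; 48.40/.41/.43/.49; 48.50/.52/.59; 48.6x), and
no other-cancer diagnosis in 140–239. Codes match by string prefix on the
dotless form (claims convention). Two carve-outs from the exclusion range:
the CRC roots themselves, and secondary-malignancy roots 196–198, which
serve as the metastasis (disease-severity) marker — without that carve-out
a cohort matched on metastasis could not be defined from codes alone.
Comorbidity flags come from diagnosis codes too (diabetes 250.x, liver
disease 571.x, alcohol abuse 303.x). Records are counted against the first
inclusion rule they fail, in the order above, giving a flow-diagram-style
attrition log.

Matching is exact, stratified on (age band, sex, metastasis), 1:4 without
replacement and without calipers: within each stratum, case order and the
control pool are shuffled by the seed and controls assigned in blocks of
four — equivalent to uniform sampling without replacement. Cases in strata
with fewer than four remaining controls are reported unmatched and
excluded. Exact matching makes the matched-on variables balance identically
(chi-square statistic 0, p = 1); variables associated with the exposure but
not matched on (diabetes above all) remain imbalanced by design. Age is
matched at the band level (20–44/45–59/60–74/75+); exact-year matching
would break 1:4 feasibility and the band is the analytically relevant unit.

## Estimation

Logistic models are fitted by Newton–Raphson maximum likelihood
(statsmodels) with score tolerance 1e-8 and at most 100 iterations;
non-convergence raises an error carrying the iteration trace, and perfect
separation is detected (library signal, plus a |β| > 30 guard). Wald 95%
CIs are formed on the log-odds scale and exponentiated, so OR = exp(β)
holds identically. Each fit reports event count, dependent-variable mean,
−2 log L, the likelihood-ratio statistic against the intercept-only model,
and a Rao score statistic of the same comparison (two conventional "model
chi-square" statistics that differ slightly in finite samples; neither is
used downstream). OLS fits report Wald CIs, R² and adjusted R². Every model
is complete-case in its own outcome, so the mortality and charges models
run on slightly fewer rows than the complication models — matching the
per-outcome missing-data accounting of administrative data.

Predictor columns that are constant in the estimation sample (e.g. a
complication that never occurs there) are dropped and recorded on the fit
rather than failing on a trivially singular design; genuinely collinear
designs are rejected.

Mediators are the complications whose obesity coefficient has two-sided
p < 0.05 in its own adjusted model, out of 13 candidates. The default
adjustment set is race, household-income quartile, elective admission,
hospital location, and teaching status (reference levels: White, Q1,
non-elective, rural, non-teaching) — the set displayed in the motivating
tables; it is fully configurable. With 13 candidates at α = 0.05 an
occasional false-positive mediator is expected on synthetic data; its
near-zero edge products barely perturb the totals, and no multiplicity
adjustment is applied (none is applied in the convention followed).

## The synthetic generator

The generator emulates NIS-like admissions with the assumed causal
structure, and its defaults are the published study conditions:

- obesity prevalence 7.86%; all other covariates drawn from
  group-conditional (obese vs non-obese) categorical distributions taken
  from the published cohort-characteristics counts. Conditioning on the
  exposure reproduces every published group difference (diabetes 40.7% vs
  18.7%, elective admission, age structure, …) without an explicit copula;
  beyond that, covariates are mutually independent within group.
- each of the 13 complications is a Bernoulli draw from a logistic model;
  the five modelled mediators use the published coefficient sets, the
  remaining eight (997.0/.1/.2/.3/.5/.7, 998.83, 998.9) are intercept-only
  with rates chosen once as claims-realistic (0.2–3.5%) and no obesity
  effect, since no estimates are published for them. Complications are
  conditionally independent given the covariates.
- death is logistic in the five mediator flags only (no direct obesity
  term); LOS and charges are linear in the same flags.
- intercepts are calibrated by monotone 1-D root finding (Brent) on the
  *exact* population-average probability — enumerating the
  obesity × covariate joint distribution (and, for the mortality model,
  integrating out the 2⁵ mediator configurations using their conditional
  independence) — to hit target prevalences of 4.6%, 0.3%, 2.1%, 1.2%,
  12.0% for the mediators and 2.2% for death. The same enumeration serves
  as the test oracle for realized rates.
- LOS/charges noise is shifted log-normal, mean zero, SD 8 days / $80,000,
  with pre-shift means of 8 days / $50,000. The left support bound (−mean)
  plus the model intercepts (8.08 days, $54,795) keeps both outcomes
  positive without clipping, so OLS coefficient recovery is unbiased; the
  right skew mimics the heavy upper tails of stay and billing data. The
  published record gives no conditional dispersion, so the noise scale is a
  free parameter anchored to the published marginal SDs and exposed in the
  config.
- outcomes are set missing completely at random at the published
  per-outcome missing proportions (death 0.057%, LOS 0.002%, charges
  2.95%). No informative-missingness mechanism is modelled.
- age is uniform within its band (75+ capped at 100); only the band enters
  any analysis.
- exposure, severity, comorbidities and complications are all *emitted as
  ICD-9-CM codes* on the records; optionally a `distractor_fraction` of
  records violate one inclusion rule each (other-cancer code, missing
  surgery code, or age < 20) to exercise extraction.

What the generator does **not** emulate: survey weights and sampling
strata, within-hospital clustering, coded-obesity under-ascertainment,
informative missingness, correlated complication onsets, or any covariate
dependence beyond exposure-conditioning. Passing tests therefore
demonstrate correctness of the pipeline's logic and estimators under the
assumed data-generating process, not robustness to those real-data
features.

## Numerical and design choices

- Chi-square tests are Pearson without continuity correction (samples are
  large; a warning is attached when an expected cell is below 5); the
  t-test defaults to the pooled-variance form (group SDs in the motivating
  tables are near-equal) with Welch available. Degenerate continuous
  comparisons (zero variance, equal means) return p = 1 rather than NaN.
- Determinism: one seed drives the generator (with a spawned child stream
  for code assignment), and the matching seed is separate and logged; a
  configuration reproduces its result bundle byte-for-byte.
- Replay mode (`from_printed_tables` / `crcpath replay`) rebuilds the path
  decomposition from published coefficients without microdata, preferring a
  supplied ∂P/∂X and otherwise evaluating β·P·(1−P).
- Problem sizes: the test suite exercises the generator at 30k–80k
  admissions, matching guarantees at 50k, and parameter recovery on five
  replicates of 200k admissions — large enough that Wald CIs are
  well-calibrated (observed coverage ≈ 97% against generating values) and
  estimated path totals land within a few percent of the plug-in truth
  Σ aᵢbᵢ.
- Display rounding: marginal effects to 4 decimals, mortality products in
  10⁻⁵ units, LOS to 3 decimals, charges to whole dollars; all internal
  arithmetic is full precision.

## Known limitations

Admissions are treated as patients (no readmission linkage). The exclusion
and severity rules live entirely in an editable codebook, but only ICD-9-CM
(not ICD-10) vocabularies ship by default. The path totals carry no
standard errors. The mediator-selection step conditions subsequent models
on a data-dependent choice, which the decomposition (like its motivating
convention) ignores.
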