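# crcpath

Marginal-effect path analysis of how obesity worsens in-hospital outcomes
after colorectal-cancer (CRC) surgery — mortality, length of stay (LOS), and
total hospital charges — by way of postoperative complications, together
with a synthetic generator of NIS-like administrative admission records so
the whole pipeline is runnable and testable without the licensed HCUP
National Inpatient Sample data.

It is aimed at biostatisticians and health-services researchers who want a
reproducible implementation of the absolute-marginal-effect mediation
approach for claims data: cohort definition from ICD-9-CM codes, exact 1:4
case-control matching, the regression layers, and the path decomposition.

## The method

Admissions with a CRC diagnosis (ICD-9-CM 153/154) and a qualifying
resection (45.7x, 48.4x/48.5x subsets, 48.6x), age ≥ 20, and no other-cancer
diagnosis form the cohort. Obese admissions (dx 278.0) are matched 1:4 to
non-obese controls exactly on age band, sex, and metastasis. Three model
layers are then fitted on the matched cohort:

1. logistic models `complication ~ obesity + covariates` for each of 13
   postoperative complication families (998.x/997.x);
2. a logistic model `death ~ the mediating complications`;
3. OLS models `LOS ~ mediators` and `charges ~ mediators`.

Complications significantly related to obesity (p < 0.05) act as mediators.
Each logistic coefficient β is converted to an **absolute marginal effect**

    ∂P/∂X = β · P · (1 − P)

at the outcome prevalence P (the dependent-variable mean). Unlike odds
ratios, these absolute effects multiply along a path: with aᵢ the
obesity → complication-i edge and bᵢ the complication-i → outcome edge
(a marginal probability for death, an OLS coefficient for LOS/charges), the
mediated contribution is aᵢ·bᵢ and the total indirect effect is Σᵢ aᵢ·bᵢ.

The synthetic generator draws admissions with exactly this causal structure
(obesity → complications → outcomes), using published coefficient tables as
generating parameters and group-conditional covariate distributions, and
encodes everything as ICD-9-CM codes so extraction and flag derivation are
exercised for real.

## Worked example

Replay mode needs no data at all — it rebuilds the path diagram from the
packaged published coefficients:

```bash
$ python examples/replay_published_paths.py
mediator                  a   b_mort  a*b mort(1e-5)  a*b LOS(d)  a*b chg($)
infection            0.0190   0.0176           33.44       0.160        1181
shock                0.0025   0.0521           13.03       0.022         213
bleeding             0.0050   0.0121            6.05       0.016         154
wound_disruption     0.0060   0.0132            7.92       0.067         521
digestive            0.0135   0.0046            6.21       0.053         316
TOTAL                                          66.64       0.317        2384
```

Reading the infection row: obesity adds 1.90 percentage points of infection
risk (a = 0.0190); an infection adds 1.76 points of death risk (b = 0.0176);
their product, 33.44 × 10⁻⁵, is the extra absolute death probability obesity
contributes *via* infection, alongside 0.160 extra days and $1,181 extra
charges. Summing the five rows: obesity raises in-hospital mortality by
66.6 × 10⁻⁵, stay by 0.32 days, and charges by $2,384 through the five
complications, infection being the dominant channel throughout.

The same decomposition estimated end-to-end from synthetic microdata:

```python
from crcpath import PipelineConfig, default_config, run_pipeline

bundle = run_pipeline(PipelineConfig(
    simulate=default_config(n_patients=60_000, seed=1), match_seed=1))
print(bundle.mediators)
print(bundle.paths.format_table())
```

which at this sample size prints mediators
`infection, shock, bleeding, wound_disruption, respiratory` (the four
strongest true channels plus, at p < 0.05 over 13 candidates, an occasional
false positive — here respiratory, whose near-zero products barely move the
totals) and totals near the replayed ones (69.8 × 10⁻⁵, 0.28 days, $2,107).

A thin CLI mirrors the stages:

```bash
crcpath simulate --n 50000 --seed 1 --out records.csv
crcpath extract --records records.csv --out cohort.csv
crcpath match --cohort cohort.csv --seed 1 --out matched.csv
crcpath run --simulate-n 50000 --seed 1 --out results/
crcpath replay --out paths.json
```

See `examples/` for narrative scripts (replay, full pipeline, matching
balance, marginal effects vs odds ratios) and `docs/methods.md` for the
modelling details and limitations.

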