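# bbmcue

Cost-utility modelling of blood-based amyloid biomarkers (BBM) in the
Alzheimer's disease (AD) diagnostic pathway, in the context of an available
disease-modifying treatment (DMT).

The package is for health economists and dementia-care researchers who want
to explore how a cheap, scalable blood test changes referral flows,
diagnostic accuracy, lifetime costs and quality-adjusted life years (QALYs)
when treatment eligibility hinges on biomarker-confirmed amyloid pathology.

## The model

A **decision tree** partitions a unit cohort of 65-year-olds presenting to
primary care (PHC) with subjective cognitive complaints. The cohort is
split by true cognitive state — subjective cognitive decline (SCD), mild
cognitive impairment (MCI), mild dementia — and true amyloid status, and
pushed through one of three diagnostic strategies:

* **SOC** — standard of care: clinician judgement refers a fraction *r* of
  MCI/dementia patients to the memory clinic (MC), where a CSF amyloid test
  sets the diagnosis;
* **BBM-PHC** — the blood test is done at primary care and every
  test-positive patient is referred for CSF confirmation;
* **BBM-MC** — referral as in SOC, but the clinic uses the blood test to
  triage who receives the invasive CSF examination.

SCD patients exit untested in every arm. The tree yields the confusion
matrix against true amyloid (TP/FP/TN/FN), referral and CSF burden, and the
per-person diagnosis cost.

A **nine-state annual Markov cohort model** (SCD, MCI, mild/moderate/severe
dementia, each dementia stage also institutionalised, and dead) then
simulates 30 years of progression. Pre-dementia progression is
amyloid-specific; mortality applies the stage hazard ratio *h* to the
age-specific death probability *q* as `1 − exp(−q·h)`. Biomarker-confirmed
(treated) patients enter treatment tunnel states for at most two years or
until moderate dementia; the DMT multiplies the MCI→mild and mild→moderate
progression probabilities by `(1 − e)` with effect `e = 0.27` for
amyloid-positive patients only — false positives pay for the drug without
benefit. Costs and utilities accrue per cycle, discounted at 3%/yr, and
strategies are compared by the incremental cost-effectiveness ratio
ICER = ΔC/ΔQALY against a willingness-to-pay (WTP) of €50,000/QALY.

The registry-derived inputs the model needs (old-age life table, dementia
transition block, stage-specific mortality hazard ratios) ship as clearly
labelled **synthetic fixtures** (bundle "F0"); real tables can be dropped in
as CSVs with the same schema.

## Worked example

```python
import bbmcue as b

params = b.ParameterSet.default()          # base case, "text" dialect
fixtures = b.default_fixture_bundle()      # synthetic registry stand-ins

soc = b.evaluate_pathway(b.PathwayId.SOC, params)
phc = b.evaluate_pathway(b.PathwayId.BBM_PHC, params)
print(f"SOC referred {soc.frac_referred:.1%}, TP {soc.frac_tp:.1%}, "
      f"diagnosis €{soc.diagnosis_cost_per_person:,.0f}")
print(f"BBM-PHC referred {phc.frac_referred:.1%}, TP {phc.frac_tp:.1%}, "
      f"diagnosis €{phc.diagnosis_cost_per_person:,.0f}")

ref, itv, ce = b.compare_strategies(b.PathwayId.SOC, b.PathwayId.BBM_PHC,
                                    params, fixtures)
print(f"ΔC €{ce.delta_cost:,.0f}, ΔQALY {ce.delta_qaly:.4f}, "
      f"ICER €{ce.icer:,.0f} ({ce.quadrant.value})")
```

prints

```
SOC referred 24.4%, TP 14.5%, diagnosis €1,874
BBM-PHC referred 32.4%, TP 24.9%, diagnosis €2,122
ΔC €960, ΔQALY 0.0159, ICER €60,217 (NE)
```

Blood testing at primary care refers 8 percentage points more patients
(+800 per 10,000 evaluated) and raises true-positive AD diagnoses from
14.5% to 24.9% of the cohort, at €248 extra diagnosis cost per person. On
the synthetic F0 fixtures the lifetime trade-off lands in the northeast
quadrant of the cost-effectiveness plane: more effective and more costly,
with an ICER above the €50,000 threshold (the lifetime figures depend on
the fixtures; only the decision-tree outcomes above are
fixture-independent). `b.price_threshold(params, fixtures)` returns the
value-based annual drug price at which the ICER exactly meets the
threshold (€4,094 on F0).

The same analyses are available from the shell:

```bash
bbmcue base-case --out out/        # intermediate outcomes + CE tables
bbmcue dsa --out out/              # one-way tornado table
bbmcue psa --iterations 10000 --seed 1 --out out/
bbmcue threshold --out out/        # value-based price
bbmcue fixtures-export --out fixtures_f0/
```

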