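# Methods

## Model structure

The model couples a one-shot diagnostic decision tree to an annual-cycle
Markov cohort simulation, evaluated over a 30-year horizon from age 65.

**Decision tree.** The unit cohort is partitioned by true cognitive state
(SCD 53%, MCI 30%, mild dementia 17%) and true amyloid status (prevalence
31% in SCD and, depending on the parameter dialect, 54.8%/84.1% or
55.5%/84% in MCI/dementia). Each of the three strategies (standard of
care, blood test at primary care, blood test as memory-clinic triage)
determines who is referred, who is blood-tested, who receives CSF, and who
ends with a biomarker-confirmed AD diagnosis. Diagnosis is a one-time
process: misdiagnosed patients are never re-evaluated. The final partition
has ten groups (state × amyloid × diagnosis label; SCD can never be
labelled AD because SCD exits primary care untested), each carrying its
mass into the Markov stage. Test results are conditionally independent
given true amyloid status: CSF accuracy does not depend on the blood-test
result, and clinician referral does not depend on amyloid.

**Markov model.** Nine health states: SCD, MCI, mild/moderate/severe
dementia in the community, the three dementia stages institutionalised,
and dead. Pre-dementia progression is amyloid-specific (SCD→MCI 0.41 vs
0.10/yr; MCI→mild 0.22 vs 0.05/yr, the amyloid-negative values derived
from the amyloid-positive ones through the progression odds ratio 5.89 via
`odds_neg = odds_pos / OR`). The six dementia states evolve by a single
transition block regardless of amyloid status; regression to a less severe
stage is allowed between dementia states but not out of MCI or mild
dementia, and there is no return from institution to community.

**Mortality (competing risk).** Death is applied first in each cycle:
SCD/MCI die at the general-population probability q(age); dementia states
at `1 − exp(−q(age) · HR(stage))`, with hazard ratios anchored at the
published very-mild-dementia excess hazard of 1.82. Surviving mass is then
split over the conditional progression probabilities, which keeps every
row stochastic. The ordering (death before progression) is a declared
convention; the source material does not specify one.

**Treatment.** A biomarker-confirmed diagnosis triggers the
disease-modifying treatment. Duration is at most two annual cycles, or
until progression to moderate dementia, tracked with tunnel copies of MCI
and mild dementia (year 1 / year 2). While on treatment the MCI→mild and
mild→moderate progression probabilities are multiplied by (1 − effect),
effect 0.27, for amyloid-positive patients; amyloid-negative (false
positive) patients occupy the tunnels — and accrue the €5,000/yr drug cost
— with zero effect. There is no residual effect after the tunnel.
Institutionalisation during the treatment window ends the tunnel: the
tunnels cover community MCI and mild dementia only. Since the modelled
effect acts solely on the two community progression probabilities and the
window is two years, the forgone effect in institutionalised mild dementia
is second-order.

**Accounting.** Costs (2022 euros, societal perspective) and utilities
accrue at cycle start: membership at the beginning of a year earns that
year's full annual cost and utility weight. A half-cycle correction
(averaging start- and end-of-cycle occupancy) is available as a switch but
off by default. Both costs and effects are discounted at 3%/yr, cycle 0
undiscounted. SCD is costed as MCI; institutionalised stages use long-term
care costs but reuse the community utility of their stage; the dead state
accrues nothing. The one-off diagnosis cost from the decision tree enters
at cycle 0. ICERs are computed from unrounded increments. In the southwest
quadrant of the cost-effectiveness plane (cheaper, less effective) the
decision rule follows the source convention — an ICER at or above the
willingness-to-pay threshold favours the comparator — which differs from
the textbook net-monetary-benefit rule; the CEAC in the probabilistic
analysis, by contrast, uses net monetary benefit.

## Parameters

All inputs live in `ParameterSet` with the base-case values of the
published parameter table; `data/default_config.yaml` reproduces them.
Two **dialects** exist for the MCI/dementia amyloid prevalence because the
source prints two slightly different sets (0.548/0.841 in prose,
0.555/0.84 in the table) and its downstream tables are internally
consistent only within a set; `"text"` is the default and reproduces the
referral/CSF/TN/FN cells, `"table1"` reproduces the triage-arm CSF
fraction. No single set reproduces every printed cell.

Parameters varied in sensitivity analyses carry a `DistributionSpec`
(family, mean, 95% bounds): beta for probabilities and utilities, gamma
for costs, fitted by method of moments with sd = (high − low)/3.92. The
SCD cohort share has no published interval; whenever the MCI or dementia
share is varied, the SCD share absorbs the change so the cohort remains a
unit mass.

## Synthetic fixtures

Three registry-derived inputs are not published and are emulated by the
`fixtures` module; every bundle is tagged `provenance="synthetic"` and the
tag is propagated to all outputs.

* **Life table** — Gompertz form q(age) = 1 − exp(−a·e^(b·age)) with
  a = 2×10⁻⁵, b = 0.11, giving q(65) ≈ 0.025 and roughly a doubling of
  mortality every 6.3 years; the implied remaining life expectancy at 65
  is about 13.5 years. This is a shape-plausible convenience, not a fit to
  any national table.
* **Dementia transition block** — a row-stochastic 6×6 block with forward
  progression, community→institution entry, small regression steps, and no
  institution→community return; rates are jittered ±20% deterministically
  from a seed around levels (progression 0.25, institutionalisation 0.08,
  regression 0.02/yr) chosen to give a median survival from mild dementia
  of about 6 years under the default bundle.
* **Mortality hazard ratios** — a multiplicative ladder from the 1.82
  anchor (step 1.4 per stage, ×1.2 when institutionalised), satisfying
  severity- and setting-monotonicity.

The versioned default bundle **F0** (seed 74) is generated in code and is
bit-reproducible. Because these stand-ins do not reproduce the registry
estimates, the model's *lifetime* outputs (total costs, QALYs, ICERs, the
probabilistic quadrant split, the value-based price) are fixture-dependent
illustrations; tests assert their structural and directional properties
(mass conservation, microsimulation agreement, ICER monotone in drug
price, specificity-driven ICER reduction), not their published values. The
decision-tree outcomes and derived transition probabilities are
fixture-free and are asserted at printed precision.

## Sensitivity analyses

One-way analysis re-runs the full two-arm pipeline at each parameter's low
and high bound and ranks parameters by ICER swing. The probabilistic
analysis draws all 23 uncertain parameters independently (no correlations
are published), re-runs both arms per iteration, and summarises the
incremental cloud: iterations that gain QALYs are split by whether their
ICER exceeds the threshold (cost-saving, QALY-gaining iterations count as
below); QALY-losing iterations are in neither fraction. Each parameter has
its own child random stream keyed by master seed and sorted position, so
adding or removing a parameter does not perturb the others' draws and
results are bit-reproducible given the seed.

## Numerical choices and problem sizes

Row sums are validated to 1 at 1e-9; cohort shares to 1 at 1e-9. The price
threshold exploits that the ICER is affine in the annual drug price (the
price enters incremental cost through discounted on-treatment
person-years), solving from two pipeline evaluations and verifying the
root to €1. The microsimulation check uses 200,000 individuals (binomial
standard errors ≲ 0.001 per occupancy cell); test-time probabilistic runs
use small iteration counts with a separate 10,000-draw check that the
sampled parameter means recover their inputs, keeping the default suite
under a few minutes on one CPU.

## Known limitations

Only AD-type dementia is modelled; no re-testing of misdiagnosed patients;
no test-sequence dependence (CSF accuracy unconditional on the blood-test
result); treatment response is all-or-nothing by amyloid status with no
effect on institutionalisation or mortality; no caregiver disutility,
adverse events, or terminal-care costs; no separate utilities for
institutionalised states; "very mild" dementia exists only as the hazard
anchor, not as a Markov state. Passing tests on the synthetic fixtures
demonstrates internal consistency of the machinery, not agreement with
registry-based lifetime results.
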