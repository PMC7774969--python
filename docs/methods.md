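# Methods

## Model structure

Five health states — NPG, IGT, DM2, CVD (diabetes with cardiovascular
disease) and death — on an annual cycle. Allowed edges: NPG ↔ IGT,
IGT → DM2, DM2 → CVD, every living state → death, self-loops; death is
absorbing. There is no DM2 → IGT reversal and no direct NPG/IGT → CVD
edge: a cardiovascular event in this model is a complication of
established diabetes.

The engine is a first-order microsimulation: each individual is walked
through cycles and a destination state is sampled from their transition
row. A cohort-level (expected-value) model would not suffice because
the utility weight depends on each person's diabetes duration; a
deterministic state-occupancy oracle exists nonetheless
(`cohort_oracle`) for the memoryless-utility variant, and the test
suite requires the microsimulation to agree with it within Monte-Carlo
error — the central correctness check.

## Transition probabilities

Published inputs are annual probabilities (control arm) plus
intervention-vs-control hazard ratios:

| quantity | value |
|---|---|
| NPG → IGT / IGT → NPG (both arms, all ages) | 0.193 / 0.192 |
| IGT → DM2, ages ≤65 / ≥66 | 0.1410 / 0.1113 (HR 0.57 / 0.61) |
| DM2 → CVD, ages 45–51 / ≥76 | 0.009 / 0.0358 (HR 0.74 from age 52) |
| mortality RR vs background, DM2 / CVD | 2.00 / 2.13 (HR 0.74 / 0.67) |

Conventions, each isolated in one function:

* **Rate-scale effects.** Hazard and relative risks multiply the rate
  −ln(1−p), never the probability. This matches the exponential
  annualization formula and matters for p > 0.1.
* **Competing risks.** Death is resolved first from the life table
  (times the state's mortality multiplier); the marginal progression
  probabilities are then scaled by the survival probability; the
  residual stays on the current state. Rows sum to 1 by construction.
* **Age bands are data.** Band tables are `(age_low, age_high, value)`
  lists with inclusive upper bounds. The published bands start at 45
  while enrolment spans 25–74, so the youngest band extends downward
  unchanged. The CVD-onset rows for ages 52–75 are not published; the
  fixture fills them by log-linear interpolation of the annual rate
  between the anchors 0.009 (at 51) and 0.0358 (at 76). The
  interpolation lives in the parameter layer, is re-derived whenever an
  anchor is perturbed, and is the single most consequential assumption
  forced by missing inputs (see Limitations).
* **Effect duration.** The intervention hazard ratios apply for the
  whole horizon, not only the six intervention years, because they
  derive from 30-year follow-up outcomes.
* The all-cause mortality hazard ratio of 0.74 printed alongside the
  life-table row is carried as data but not applied as an extra
  multiplier: intervention mortality benefit enters only through the
  DM2/CVD state hazard ratios, NPG/IGT carry plain background
  mortality in both arms.

## Background mortality

A life table supplies annual death probabilities `qx` by single year of
age, terminal `qx = 1`. CSV input may be single-year or abridged;
abridged bands expand under a constant within-band hazard, which
conserves band survival exactly. The bundled synthetic table is
Gompertz–Makeham, μ(x) = λ + a·e^{bx}, with λ = 5·10⁻⁴ and b = 0.095
fixed (adult mortality doubling time ≈ 7.3 y) and only `a` calibrated,
by bisection, so that life expectancy at birth is 76.5 years (±0.05) —
the one population figure available to calibrate against. The table is
unisex; a sex split is not published for the cohort. Life expectancy
uses the half-year convention for within-year deaths.

What the synthetic table does *not* emulate: infant/child mortality
structure, cohort (generation) effects, and the true sex-specific
Chinese period tables the original analysis used. Absolute life-year
levels therefore carry a table-shaped uncertainty; comparisons between
arms (the quantities of interest) are much less sensitive.

## Rewards

**Utilities** (weights at age 45: NPG 0.936, IGT 0.931, diabetes onset
0.925, CVD 0.779) decline by 0.003 per year of age in NPG/IGT. Once
diabetes is established the age decrement is taken to the age at onset
and 0.003 is subtracted per year of diabetes duration; CVD subtracts a
further 0.158. For onset at age ≥ 45 this is identical to a pure age
decrement, which is why the memoryless oracle variant is exact at a
fixed entry age of 45. The published worked example is reproduced
literally through the `dm2_base` override: 0.832 − 0.158 − 10·0.003 =
0.644. The separate DM2 decrement of 0.012 is carried as data but not
applied on top — 0.936 − 0.012 ≈ 0.925, i.e. the onset weight already
embodies it. Utilities are floored at 0.

**Costs** (2016 ¥): DM2 6,436/yr; CVD 6,436 + 11,680/yr (the state is
diabetes *with* CVD; a single-cost mode exists because the published
unit costs carry no composition rule). The intervention arm adds the
program cost of 3,374 amortized uniformly over the six intervention
years (lump-sum-at-entry mode available; at 3 % discounting the
difference is < ¥90) and 422/yr screening for every year alive
(six-year-only mode available; the full-horizon default reflects
health-management services continuing under the primary-care reform
framing).

**Accrual.** The entry cycle is cycle 1; cycle-t rewards are discounted
by (1+r)⁻ᵗ, with r = 3 %/yr for both costs and effects. Half-cycle
correction credits a transition cycle with the mean of origin- and
destination-state rewards; death counts as zero reward, so a death
cycle credits half the origin reward and half a life-year. Life-years
are never discounted (the published 30-year life expectancies are
consistent only with undiscounted years). The oracle uses the
identical rules, so microsimulation-vs-oracle agreement validates the
accrual code path, not just the transition arithmetic.

**Onset delays** are differences in restricted mean time to first
entry into DM2 (or CVD), with persons never reaching the state
contributing the 30-year restriction window.

## Randomness and reproducibility

Every individual owns an RNG substream seeded by `(master_seed, arm,
person_id)`, so results are independent of execution order and
bit-reproducible. Both arms share one cohort draw (common ages);
transition streams are independent between arms. Sensitivity analyses
re-run all settings under a common master seed, so one-way deltas and
threshold bisection see parameter effects, not reseeding noise; in the
probabilistic analysis only the parameter draw varies across
iterations, which makes the all-distributions-fixed case collapse
exactly to the base case.

## Sensitivity analyses

* **One-way:** ±20 % on cost parameters and the IGT utility, discount
  rate 1–5 %, intervention-effect hazard ratios at their 95 % CI
  bounds; results tornado-ordered by ICER range. Published per-row CIs
  are not reproduced (their construction is unstated); uncertainty is
  the PSA's job.
* **Threshold:** bisection on the smoothed (common-seed) ICER, with an
  explicit endpoint sign-change check.
* **Scenario:** the whole cohort entering in NPG (universal screening
  of normoglycaemic adults).
* **PSA:** beta for probabilities and utilities, gamma for costs,
  lognormal for hazard/relative risks with σ = (ln hi − ln lo)/3.92;
  moment-matched from the 95 % CIs; parameters without a published
  interval use ±20 % of the central value as the interval; the
  one-time program cost is fixed. 1,000 iterations by default; CEAC on
  a WTP grid containing ¥37,446.

## Problem sizes

Default cohort 10,000 per arm (the original trial's 576 participants
would leave the incremental means dominated by Monte-Carlo noise; at
n = 10,000 the standard error of the incremental QALY is ≈ 0.03). The
microsimulation-oracle comparison runs at n = 50,000 at a single entry
age. Unit tests use cohorts of 150–6,000, chosen so each check's
Monte-Carlo interval is decisive for the property under test.

## Known limitations

* With the full published transition structure — IGT → NPG backflow of
  0.192/yr and competing background mortality — the simulated 30-year
  cumulative DM2 incidence in controls is ≈ 80 %, not the published
  97.1 %. The 97.1 % figure annualizes to 0.1113 only under pure
  absorbing IGT → DM2 progression (removing backflow and
  death-censoring yields ≈ 98.5 % here), so the printed inputs cannot
  jointly reproduce the printed validation statistic. Quantities that
  scale with DM2 occupancy (30-year incremental QALYs/life-years,
  absolute cost levels) land below the published values for the same
  reason; lifetime incrementals and the DM2 onset delay are
  insensitive to it and do match.
* The interpolated CVD-onset bands (52–75) generate little mid-age CVD
  incidence, so the between-arm CVD onset delay is smaller than the
  published 1.77 y. The unpublished intermediate rows of the original
  model cannot be recovered from the two printed anchors.
* Microvascular complications, non-medical and indirect costs are out
  of scope, as in the source analysis; the ICER is therefore
  conservative from a societal perspective.
* The synthetic life table substitutes for unpublished sex-specific
  period tables (above).
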