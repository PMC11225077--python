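# Model and methods

## Scope

`polypill_cea` implements a cost-utility decision model for primary
prevention of cardiovascular disease: a fixed-dose four-component
combination pill (aspirin 81 mg, hydrochlorothiazide 12.5 mg,
atorvastatin 20 mg, and valsartan 40 mg or enalapril 20 mg) compared
with each component given alone, in a hypothetical Iranian cohort
entering event-free at age 35 and followed over a lifetime horizon.
Outcomes are per-person discounted lifetime cost (USD) and
quality-adjusted life-years (QALYs); decision statistics are ICERs with
strict and extended dominance, net monetary benefit (NMB), one-way
tornado sensitivity analysis, Monte-Carlo probabilistic sensitivity
analysis (PSA) and cost-effectiveness acceptability curves (CEACs).

## Cohort model

A deterministic Markov cohort with annual cycles over nine states:

* **event-free** (entry state),
* five **chronic** states: stroke, heart failure (HF), post-MI,
  post-angina, peripheral vascular disease (PVD),
* two one-cycle **tunnel** states, acute MI and acute angina, which
  price and weight the event year separately before feeding the
  corresponding post state,
* absorbing **dead**.

Each cycle, an event-free person faces competing first-event risks
(stroke, HF, MI, angina, PVD), background life-table mortality, and an
additional disease-specific death hazard (0.015/year at baseline).
Incident stroke, HF and MI split into an immediately fatal share (case
fatality 0.19 for stroke, 0.17 for HF; MI fatality age- and
sex-dependent, blended 50/50 male/female by default) and a nonfatal
share that enters the event state.  Transition rows are built by
residual mass — the probabilities of leaving a state are summed and the
remainder stays — so rows are exactly stochastic; a draw or
configuration whose competing exits exceed one raises an error naming
the age and state rather than being silently renormalized.

Occupants of chronic and acute states face background mortality
inflated by a disease-specific standardized mortality ratio,
`1 - (1 - qx)^SMR`, and otherwise remain (tunnels advance to their post
state).  There are no transitions between event states.

Rewards per cycle: QALYs accrue as occupancy-weighted state utilities
(event-free utility fixed at 1, dead at 0) and costs as
occupancy-weighted state costs plus the annual medication cost of the
arm in every alive state.  Acute MI and acute angina carry their event
costs in the tunnel year only; the post states carry no state cost
(none is defined for them).  Costs discount at 5.8 %/year and QALYs at
3 %/year with start-of-cycle factors `(1+r)^-t`.  Half-cycle correction
(averaging start- and end-of-cycle occupancy in the reward step) is on
by default and switchable off; the closed-form oracle tests run with it
off.  The horizon is age 35 to 100 (65 cycles); totals are per person.

## Treatment effects

Each arm carries relative effects on the five event risks (hazard
ratios for the combination and hydrochlorothiazide, risk ratios
otherwise).  Both kinds are applied on the constant-rate scale,
`p' = 1 - (1-p)^e`, a single convention that is hazard-correct and
numerically indistinguishable from multiplicative scaling at these
annual risks.  Event/arm pairs never studied default to a null effect
of 1.0 and are listed in every run's validation report.  The valsartan
arm has no published effect block or price of its own and borrows
enalapril's (same renin-angiotensin target; the trial treated the two
as interchangeable).

The disease-specific death hazard is scaled per arm by the geometric
mean of that arm's studied event effects, on the same rate scale.  This
places the hazard in the event-free state only (avoiding double
counting with the SMRs) and assumes an arm that lowers every event risk
lowers cardiovascular background death commensurately.

## Inputs and their distributions

Inputs are a flat YAML configuration (the shipped
`data/base_case.yaml` carries the full published input table).  Each
uncertain input is a printed mean and SD plus a family — Beta for
probabilities and utilities, Gamma for costs, log-normal for relative
effects — converted to sampleable parameters by the method of moments:

* Beta: `nu = m(1-m)/sd^2 - 1`, `alpha = m*nu`, `beta = (1-m)*nu`;
* Gamma: `shape = m^2/sd^2`, `scale = sd^2/m`;
* log-normal: `sigma^2 = ln(1 + sd^2/m^2)`, `mu = ln m - sigma^2/2`,
  reading the printed value as the arithmetic mean (a config switch
  selects the median convention instead).

Two defects of the printed input table are handled explicitly:

* **Infeasible Beta SDs.**  Most utility rows print SDs close to their
  means, violating `sd^2 < m(1-m)`.  Sampling caps such SDs at
  `0.95 * sqrt(m(1-m))`, preserving the printed mean; every capped
  input is flagged in the run manifest and validation report.  The
  capped distributions are extreme (U-shaped), so PSA spread should be
  read as an upper bound on parameter uncertainty.
* **SMRs printed as Beta.**  Standardized mortality ratios exceed 1 and
  cannot be Beta-distributed; they are carried as Gamma with the same
  moments (disclosed in the validation report).

The event-free utility (printed "1 1") is a fixed point mass: a utility
of exactly 1 with Beta uncertainty is degenerate.

**Ranged inputs.**  MI, angina and PVD risks and MI case fatality are
published as `[low, high]` ranges over the adult age span.  They vary
linearly with age from the cohort entry age (35) to age 85
(`settings.risk_span_end`) and stay clamped at the upper bound beyond —
the worked values of the model fix 85, the top of the age range of the
risk equations behind the ranges, as the ramp end while the cohort runs
to 100.  In the PSA each ranged input is drawn comonotonically: one
uniform quantile per iteration drives the Beta fits of both endpoints,
keeping the sampled range ordered.

## Synthetic life table

National single-age mortality is not published with the inputs, so the
package generates a stand-in: a Gompertz hazard
`h(age) = h0 * 2^((age-35)/8)` (log-linear adult mortality, doubling
every 8 years), with `q(age) = 1 - exp(-h(age))` and the terminal age
forced to `q = 1`.  The baseline `h0` is solved so remaining life
expectancy at 35 equals 42 years, a plausible national value for the
study period.  The stand-in reproduces the *shape* of adult mortality
but none of a real table's cohort effects, sex structure or infant/old
-age irregularities; absolute cost and QALY totals move with it, while
incremental comparisons between arms are far less sensitive.  A real
life table can be supplied as a CSV (`age,qx`) via the config.

## Medication costs and the calibrated scale

Pack prices are printed per 10 tablets.  Three cost models are
provided: `per_tablet_daily` (price/10 per day, 365 days — over 1,500
USD/year for the combination), `per_pack_monthly` (one pack per month),
and `calibrated` (per-tablet-daily scaled by a single config factor).
Taken at face value the pack prices are inconsistent with per-person
lifetime totals of a few hundred USD, so the base case uses the
calibrated model with the scale solved (cost is affine in the scale —
an exact two-run solve) so the combination arm's lifetime total equals
its published 871 USD benchmark.  With the shipped inputs that anchor
lies *below* the arm's state-cost floor (1,784.7 USD at zero drug
cost), so the solve clamps at the zero lower bound: the shipped
`drug_cost_scale` is 0.0 and base-case comparisons are driven entirely
by event and state costs.  The hydrochlorothiazide arm doses 12.5 mg
against a 25 mg pack price, so it is costed at half a tablet per day.

## Decision statistics

`incremental_analysis` sorts arms by cost, removes strictly dominated
arms, then removes extendedly dominated arms until pairwise ICERs
increase along the frontier; exact ties keep the alphabetically earlier
label.  A frontier that collapses to one arm marks it dominant.  The
algorithm is property-tested against an independent greedy
smallest-ICER-step construction on random instances.

The tornado varies each input (ranged inputs as a unit, probabilities
and utilities clamped to [0, 1]) by ±20% around its mean — symmetric
variation by default, an increase-only variant by flag — and ranks
inputs by the induced spread in incremental NMB (default) or the
pairwise ICER.  The default comparison is polypill versus enalapril.

The PSA draws all uncertain inputs jointly and independently (no
correlation structure is published), one shared draw vector per
iteration across arms, with a full cohort run per arm.  Iterations
whose drawn competing risks are jointly infeasible are resampled
(bounded at 100 rounds; the count is reported — about 8–10% of
iterations at base case, driven by capped-SD draws of the ranged risks).
The default is 5,000 iterations; all randomness flows from named,
seeded streams, so runs are bit-reproducible.  CEAC probabilities are
the fraction of iterations in which an arm attains strictly maximal NMB,
with exact ties split equally, and therefore sum to one across arms at
every threshold.  The willingness-to-pay threshold is 21,768 USD/QALY
(three times GDP per capita for the study year).

## Numerical choices

* Probability arithmetic broadcasts over numpy arrays; the
  deterministic run and the PSA share one code path (the PSA is a
  single vectorized run per arm over all draws).
* Transition rows are stochastic by construction; tests enforce row
  sums and cohort conservation to 1e-12 and agreement with independent
  cycle-by-cycle enumeration of small chains to 1e-10.
* The Gompertz life-expectancy calibration and the drug-cost scale are
  exact one-dimensional solves (monotone bracketing root-find; affine
  two-point solve).
* Degenerate inputs: fixed (zero-SD) specs are never sampled; a Beta
  mean of exactly 0 or 1 must be declared fixed.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis assumes
— monotone adult mortality with a stated life expectancy, linear
age-ramps between published risk bounds, distribution families with the
published first two moments.  It does not reproduce the patient-level
risk-factor profiles, the real national life table, or any correlation
between inputs.  Passing tests therefore demonstrate that the machinery
(propagation, rewards, dominance, sampling, acceptability) is correct
under the documented assumptions, not that the absolute totals match
what a registry-grade input set would produce.

## Known limitations

* **The published input table does not reproduce the published headline
  outputs.**  Run end to end, the shipped inputs give the combination
  arm 1,784.7 USD and 17.39 QALYs (benchmarks: 871 USD, 14.55 QALYs)
  and a ~23% probability of cost-effectiveness at the threshold
  (benchmark: 92%), and the hydrochlorothiazide arm — whose printed MI
  effect (HR 0.34) is roughly twice as strong as the combination's
  (0.66) while MI is by far the costliest state — comes out cheapest
  and most effective instead of the combination.  The gap is structural:
  the unpublished life table and age-risk profiles, the implausibly
  large printed SDs, and pack prices irreconcilable with lifetime
  totals.  `scripts/acceptance.py` recomputes and reports these
  quantities honestly rather than forcing them to the benchmarks.
* One-way sensitivity is dominated by the MI effect parameters for the
  same reason; state utilities, being shared across arms within a
  comparison, largely cancel in incremental outcomes.
* No adherence/discontinuation, adverse events, between-event
  transitions, or microsimulation variance; proportions only.
* PSA draws are independent across inputs; real joint uncertainty
  (e.g., correlated utilities) is not modelled.
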