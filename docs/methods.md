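# Methods

## Decision problem and model structure

The package evaluates an integrated disease management (IDM) programme for
high-risk, exacerbation-prone COPD patients against usual care (UC) in a
cost-utility framework. Disease severity is modelled on the spirometric
GOLD II–IV scale as a forward-only Markov chain with an absorbing death
state and annual cycles: in one cycle a patient remains in state, moves to
the next state, or dies. Disease progression is treatment-independent (the
programme manages the disease, it does not restore lung function); the
programme acts through per-(arm × state) probabilities of exacerbation and
of urgent-care / emergency-room / hospital use given exacerbation, through
the mean number of visits per service among exacerbators, and through
arm-specific health-state utilities.

Within a cycle the order of operations is: (1) progression transitions,
(2) death, (3) accrual by end-of-cycle survivors of one life year, the
state×arm utility, and the expected annual service cost; decedents accrue
nothing that cycle. Cycle t (1-indexed) is discounted by (1+r)^−(t−1) — the
first cycle undiscounted — at r = 1.5%/year; no half-cycle correction.
These conventions reproduce the published one-year results, where the
utilities and costs scale with the 0.97 end-of-year survival.

The engine computes cohort expectations (second-order uncertainty only):
each Monte-Carlo replication draws one value per *parameter* and runs the
deterministic cohort trace with it. No patient-level (first-order)
variability is simulated.

## Inputs and distributions

All inputs live in a single JSON configuration (bundled default:
`src/copdcea/data/default_config.json`); scenarios are config deltas.

| role                                | family        | parameterisation |
|-------------------------------------|---------------|------------------|
| probabilities (transition, events)  | beta          | raw (event, non-event) counts; 0.1 pseudo-count for empty cells |
| unit costs, programme cost items    | gamma         | (shape, scale); programme items have CV 20% |
| mortality RR, death HR, visit counts| lognormal     | 95% CI bounds: mu=(ln l + ln u)/2, sigma=(ln u − ln l)/(2·1.959964) |
| utilities                           | resample      | finite pool per (arm × state), drawn with replacement |
| discount rate, WTP, ER fee, filters | fixed         | point value |

Deterministic runs use the printed base estimates (pool means for
utilities); probabilistic runs sample the families above. For CI-specified
lognormals the sampling mean differs slightly from the printed base — the
base is an empirical mean, the CI defines the uncertainty distribution —
and this is deliberate. One printed gamma cost item (urgent-care
laboratory/diagnostic, $19.62 vs shape×scale = 19.97) is internally
inconsistent by 1.8%; validation therefore checks gamma mean consistency at
2% rather than 0.5%. The GOLD IV mortality RR's printed base (4.24) lies
outside its own printed 95% CI (1.496, 3.921); per the rule above, PSA
draws follow the CI.

Probabilities are clamped to [0,1] after sampling (a no-op for beta).
Common parameters (transitions, RR/HR, unit costs) use one draw per
replication shared by both arms; this pairing is what makes the Monte-Carlo
intervals of the *increments* as tight as the published ones. Every
parameter has its own counter-based substream of the root seed, so a
scenario that overrides one parameter leaves all other draws untouched.

## Mortality

Annual all-cause death probabilities q(age) come from a life table. GOLD
relative risks act multiplicatively on the hazard scale,
p = 1 − exp(−r₀·m·RR) with r₀ = −ln(1−q), which keeps probabilities in
[0,1] even for RR·HR ≈ 11 at old ages; the hospitalised pathway further
multiplies the hazard by the state's HR (GOLD III and IV share one HR).
The per-cycle death probability blends the two by the exposure
h = P(exac)·P(hosp | exac) of the current arm/state draw — the only
arm-dependence of mortality.

The original life table is not published. The bundled fixture
(`life_table_synthetic.csv`, ages 40–105) is a synthetic stand-in:
log-linear (Gompertz-like) interpolation through plausible Ontario-level
both-sex anchors, calibrated so period life expectancy at 60 matches the
official ≈25.4 years. One-year (trial-horizon) analyses are insulated from
the fixture: a baseline-hazard multiplier m is bisected so the usual-care
cohort's deterministic life years equal the published 0.97. Thirty-year
results are fixture-dependent.

Known limitation: the arm-differential mortality (incremental life years)
is sensitive both to the fixture and to how RR and HR combine, which the
source does not state. The rate-multiplicative RR×HR rule used here gives
ΔLY ≈ 0.34 over 30 years versus the published 0.244 (the alternative
reading, HR replacing RR for the hospitalised pathway, gives 0.06 and fits
every other quantity worse). All other base-case outputs (per-arm life
years, costs, QALYs, ΔC, ΔQALY, net benefit, CEAC) land within ~5% /
5 percentage points of the published values; ΔQALY and net benefit sit at
the upper edge of that band because the ΔLY excess feeds them.

## Utilities

Trial utilities derive from four CAT items (chest tightness, activity,
confidence, energy) mapped linearly to EQ-5D; `cat_to_eq5d` applies a
user-supplied coefficient set (the published coefficients live in the
source's supplementary material and are deliberately not bundled — tests
use synthetic stand-ins). Because patient-level utilities are unavailable,
each (arm × state) pool is reconstructed from the printed summary
(min, median, max, mean) at the trial cell sizes implied by the beta counts
(UC 44/22/7, IDM 47/19/4 for GII/GIII/GIV).

Pool construction is deterministic: min, median (twice, for even n) and max
are placed exactly; interior points sit at the quantiles of a triangular
distribution with support [min, max] and mode at the median — the standard
three-point model for a quantity known by minimum/most-likely/maximum; a
uniform fill would treat the extreme order statistics as typical mass and
overstate dispersion (it inflates the per-replication sd of ΔQALY by ~20%
relative to what the published Monte-Carlo intervals imply). Within-block
quantile levels are then warped by a shared power exponent, bisected until
the pool mean matches the printed base estimate within 10⁻³. Each PSA
replication resamples one utility per (arm × state), held constant across
cycles — a parameter-uncertainty draw, matching the published CEAC/EVPI
dispersion; resampling a pooled *mean* would collapse decision uncertainty
to nearly zero and is inconsistent with the published 78.78% CEAC value.

## PSA, CEA statistics and value of information

`run_psa` evaluates both arms on shared draws; `summarize` reports means
with two bands: the 95% standard-error band of the MC mean (the published
increment intervals are of this kind) and the 2.5/97.5 percentile of
replications. Dominance labels follow sign logic; net monetary benefit is
ΔQALY·WTP − ΔC; the CEAC is the fraction of replications with strictly
positive incremental net benefit (ties conservatively not cost-effective)
on a $0–$100,000 grid in $500 steps (published optima fall at $2,000 and
$7,000, requiring sub-$1,000 resolution).

EVPI per patient is E[max_a NB_a] − max_a E[NB_a]. EVPPI for a parameter
subset uses a regression metamodel: fit the incremental net benefit on the
subset's standardized draws (linear by default; an additive cubic variant
is provided because linear metamodels can understate EVPPI), then
E[max(0, fitted)] − max(0, E[fitted]). A logistic companion model of the
cost-effectiveness indicator identifies decision drivers; it is an
explorer, not the EVPPI estimator. Absolute EVPI/EVPPI dollar values
depend on the reconstructed utility pools and are validated structurally
(non-negativity, EVPI ≥ EVPPI, enumeration equivalence, the utility subset
ranking first) rather than against published dollars; for reference, the
trial-horizon EVPI computes to ≈$700 at $50,000/QALY versus the published
$809.

## Scenarios

`trial_1y` (1 y, age 68, 100% GOLD II, calibrated survival; the mixed-start
variant `trial_1y_mixed_start` uses the trial's 44/22/7 baseline split),
`base_case_30y` (30 y from age 60), `horizon_5`/`horizon_10` (age 60),
`horizon_20` (age 68), `discount_5pct`, `double_treatment_cost` (programme
items ×2, all other draws untouched), `idm_utility_floor` (IDM utility
draw floored at the paired UC draw), `equal_utility` (IDM utilities set to
UC draws; CEAC read at WTP 0, i.e. P(cheaper)), `reps_10000`. Mortality is
calibrated only for the trial-horizon scenarios; all others use the
fixture directly.

## Synthetic trial generator

`copdcea.synthetic` emulates the patient-level data behind the input
table: per (arm × state) cell, Bernoulli exacerbation; conditional on
exacerbation, Bernoulli service use and zero-truncated geometric counts
among users, scaled so the mean count among exacerbators matches the
truth (the geometric family is a declared nuisance — the analysis consumes
only means and CIs); CAT items are binomial(5, p) scores with p increasing
in severity. Printed service probabilities and means are rounded
independently and can violate mean ≥ probability by a hair; the default
generator clamps the probability to the mean. The generator does not
simulate longitudinal CAT trajectories, dropout, or visit schedules, so
passing recovery tests demonstrate estimator correctness under the model's
own assumptions, not robustness to real-data features.

Estimators mirror the table's conventions: beta parameters are raw
(event, non-event) counts with a 0.1 pseudo-count for empty cells;
visit-count means carry a log-scale 95% CI (percentile bootstrap of the
mean when zero counts are present). Recovery reports judge the raw event
fractions — the pseudo-count is a smoothing convention for degenerate
cells, not the point estimator, and judging it directly would show
spurious bias in near-saturated cells (e.g. 6-patient GOLD IV).

## Numerical choices and problem sizes

Monte-Carlo runs use N = 5000 replications (the published design) —
vectorised across replications, a 30-year two-arm PSA takes well under a
second. Calibration bisects the hazard multiplier over [10⁻⁶, 10³] in log
space to |LY − target| < 10⁻⁶. Pool-mean bisection runs 200 iterations
over warp exponents [0.02, 50]. The acceptance tests run the trial and
base-case scenarios once each at N = 5000 (seed 1) and the
parameter-recovery loop at 500 replications of the full 143-patient trial.
The normal 97.5% quantile is taken as 1.959964 throughout.
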