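# Methods

## Model structure and assumptions

The model is a discrete-time Markov cohort model with a 1-year cycle and
nine states: inactive, moderately active, recommended activity (< 200,
200–450, > 450 self-reported MET-min per week), colorectal cancer, coronary
heart disease, type 2 diabetes, stroke, depression, and death. A closed
cohort (default 10,000 per arm, no entry, no ageing) starts in the activity
states with proportions 0.175 / 0.105 / 0.720 and is propagated by
arm-specific annual transition matrices. Structural assumptions:

- at most one chronic condition at a time, entered only from an activity
  state, with no recovery; the only exit from a disease state is death at a
  constant annual disease-specific mortality;
- death is reachable from every living state and absorbing;
- no background-mortality ageing, no tunnel states, no half-cycle
  correction (transitions are modelled as occurring at cycle boundaries and
  payoffs accrue on end-of-cycle occupancy);
- the intervention affects only the activity transitions; both arms share
  all other parameters. After the configured effect duration
  (`effect_duration_years`, default the whole horizon) the intervention arm
  reuses the control arm's activity transitions — occupancy is unchanged at
  the switch, only the matrix changes.

## Activity-row construction

For activity state *i* the annual probability of disease onset
(five conditions) and of death are fixed inputs; their sum leaves an
"available" mass `aᵢ = 1 − Σ_d inc_{i,d} − mort_i` (0.94–0.95 for the
packaged inputs). The arm's move probabilities to the other two activity
levels are taken at face value; the probability of staying is the residual
`aᵢ − Σ moves`. When sampled or estimated moves exceed `aᵢ` (possible
because moves and incidence are estimated from different sources, and
routinely for sampled beta draws), the moves are rescaled proportionally
into the available mass and the stay-probability is zero; the rescale
factor is recorded on the `TransitionMatrix` and logged by the CLI. This
construction guarantees row-stochastic matrices for every admissible input
and is applied identically in the deterministic and probabilistic paths,
so the all-fixed degenerate PSA reproduces the deterministic increments
bit-exactly.

## Deterministic analysis values

Every trial-derived parameter is stored with both its reported central
value and its PSA distribution, and the two deliberately disagree slightly
(e.g. a transition printed as 0.18 alongside Beta(4.0, 17.0) with mean
0.190). The deterministic engine evaluates **activity transitions at their
beta-distribution means**: the beta parameters encode the observed arm
fractions — their row sums lie within 0.1–0.8% of one — while the reported
probability column is rounded to about two significant figures and does
not form consistent row distributions. Utilities and costs are evaluated
at their **reported point values**, which are the trial means; their
beta/gamma fits match those means only to moment precision. The rounded
transition values remain available (`kind="point"`) for audit, and the
published cohort totals are reproduced within 2% under these conventions
(base-case ICER ≈ 5,203 EUR/QALY against the published 5,206).

## Discounting

Costs and effects are discounted at an annual rate (default 3.5% each,
configurable separately). Payoffs accrued during cycle t carry the factor
`(1+r)^-(t-1)`: the first model year is undiscounted, which is the
convention that reproduces the published five-year totals (≈ 4.05
discounted QALYs per person). The one-off program cost (EUR 260 per
intervention participant) is incurred at enrollment, time zero,
undiscounted.

## Probabilistic sensitivity analysis

Each of the 25,000 default draws samples:

- the six off-diagonal activity-move probabilities per arm from their beta
  distributions, independently per arm (the stay-probabilities are
  determined residually by the kernel above, so their distributions are
  carried but not sampled);
- the three activity-state utilities (beta) and three activity-state
  annual costs (gamma) once per draw, shared by both arms — they describe
  the same states in the same population, so sampling them per arm would
  inject spurious between-arm noise;
- nothing else: literature-sourced inputs (disease incidence, all
  mortalities, disease utilities and costs, program cost, literature
  utilities) are fixed by design.

Matrices are rebuilt per draw with the same kernel as the deterministic
engine, both arms are rerun, and the incremental cost/QALY pair is
recorded. Failures abort with the draw index rather than being skipped.
Reproducibility: draw *i* uses the *i*-th spawned child of
`numpy.random.SeedSequence(seed)`, so results are bit-reproducible for a
given seed and enlarging `n_sims` extends rather than reshuffles the draw
sequence.

Summaries: 95% credibility intervals are empirical 2.5/97.5 percentiles
with linear interpolation between order statistics (`numpy.percentile`,
`method="linear"`). CEACs report the fraction of draws with strictly
positive net monetary benefit λ·ΔE − ΔC on a willingness-to-pay grid of
0–50,000 EUR/QALY in steps of 1,000, which contains the commonly quoted
10,000 / 22,000 / 34,000 thresholds. Because ΔE is right-skewed, its mean
sits below the credibility-interval midpoint; interval endpoints, not
midpoints, are the reported uncertainty summary.

## Scenario and deterministic sensitivity analyses

Canonical scenarios (each a pure override set on the base case): 10-year
horizon with the effect maintained throughout; healthcare instead of
societal cost perspective; literature activity utilities (0.80 / 0.87 /
0.91, fixed) instead of trial utilities; one-year intervention effect.
Discount-rate variants cover 0% and 5% applied to costs only, effects only,
and both. The tornado output reports each scenario's ICER and its percent
change versus base; dominant scenarios keep their signed negative ICER and
are flagged rather than suppressed.

## Synthetic-trial generator

`generate_trial` emulates the data-generating process the transition
inputs assume: per arm, baseline categories are multinomial in the
population activity distribution and 12-month categories follow a known
row-stochastic transition matrix. Defaults mirror the modelled population
(initial split 0.175 / 0.105 / 0.720; arm size 550, about the scale of a
multicentre lifestyle RCT arm). `estimate_transitions` recovers row-wise
fractions with conjugate-count betas (α = transitions, β = row remainder);
cells with zero counts on either side are returned as fixed values and
flagged degenerate. What the generator does *not* emulate — loss to
follow-up, measurement error in self-reported activity, within-club
clustering, covariate-driven heterogeneity — bounds what passing tests
show: they validate the estimation arithmetic and its sampling behaviour,
not robustness to real-trial imperfections.

## Numerical choices and problem sizes

- Transition-matrix rows are asserted to sum to 1 within 1e-12 and cohort
  mass to be conserved within 1e-6 persons at every cycle.
- The microsimulation validator propagates individuals by multinomial
  sampling with the same matrices; the cohort trace is checked to lie
  within three standard errors of its sampling noise at one million
  individuals.
- Validation errors name the offending parameter; unknown configuration
  keys are rejected rather than ignored.
- Default problem sizes are the analysis's own: cohort 10,000 per arm,
  25,000 PSA draws; the full acceptance recomputation (two 25,000-draw
  PSAs plus all deterministic analyses) completes in well under a minute
  on a single core.

## Known limitations

The model inherits the published design's simplifications: no
comorbidity, no recovery from chronic conditions, constant (non-ageing)
mortalities and incidences, intervention effects confined to activity
transitions, and possible double-counting between activity-level and
disease-specific mortality. The residual-stay kernel and first-year
undiscounted convention were chosen to reproduce the published totals;
other defensible conventions (proportional rescaling of all three activity
entries, discounting from year one) shift the base-case ICER by roughly
±4%, which is the right order of magnitude to keep in mind when comparing
against other implementations.
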