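# fitcea

A Markov cohort cost-effectiveness model of the EuroFIT physical-activity
program for men versus no intervention, for health economists and
modellers who want a fully declarative, reproducible implementation of the
published decision model.

## The model

EuroFIT is a 12-week lifestyle program delivered through professional
football clubs that increases men's physical activity. Because the trial
followed participants for only 12 months, the longer-term value of the
program is assessed with a decision-analytic model: a discrete-time Markov
cohort model with nine mutually exclusive health states — three activity
levels (inactive < 200, moderately active 200–450, recommended > 450
MET-min/week), five chronic conditions associated with inactivity
(colorectal cancer, coronary heart disease, type 2 diabetes, stroke,
depression), and death. A closed cohort of N = 10,000 men per arm starts
distributed over the activity levels (17.5% / 10.5% / 72.0%) and is
propagated over annual cycles t = 1..T (T = 5 in the base case) by
arm-specific transition matrices **P**ₐ:

- activity → activity moves use the trial-arm transition probabilities,
  conditioned on the competing annual probabilities of disease onset and
  death (the stay-probability is the residual mass);
- activity → disease and → death entries are fixed literature-sourced
  annual probabilities;
- disease states are absorbing except for disease-specific mortality;
  death is absorbing.

Each cycle accrues, per person in state *s*, a utility u(s) (QALYs) and an
annual cost c(s) (EUR 2017, societal or healthcare perspective), discounted
at rate r = 3.5%:

```
E = Σₜ occupancyₜ · u · (1+r)^-(t-1)      C = Σₜ occupancyₜ · c · (1+r)^-(t-1) + N·c_program
ICER = (C_eurofit − C_control) / (E_eurofit − E_control)
```

Parameter uncertainty is propagated by Monte Carlo probabilistic
sensitivity analysis (25,000 draws: beta distributions for trial-derived
transition probabilities and utilities, gamma for costs) and summarised as
95% credibility intervals and cost-effectiveness acceptability curves
(CEACs), the probability that the net monetary benefit λ·ΔE − ΔC is
positive as a function of the willingness-to-pay λ.

All inputs ship as a packaged YAML fixture ([reference
parameters](src/fitcea/data/reference_parameters.yaml)); no external data
are needed.

## Worked example

```sh
$ fitcea base --out-dir out
incremental cost 663,040 EUR, incremental QALYs 127.4, 5,203 EUR/QALY
```

Over five years the intervention cohort accrues ~127 extra QALYs and
~EUR 663k extra cost (of which EUR 2.6M is the program itself at EUR 260
per participant, partly offset by costs avoided through higher activity),
i.e. about EUR 5,200 per QALY gained — far below the EUR 22,000–34,000
per QALY range health-technology-assessment bodies typically accept.
Extending the horizon to ten years flips the sign of the cost difference:

```sh
$ fitcea scenarios --name horizon_10y --out-dir out
   scenario  ...  incremental_cost  incremental_qalys         icer  verdict
horizon_10y  ...     -2.544401e+06         375.301804 -6779.612072 dominant
```

the program then saves ~EUR 2.5M while gaining ~375 QALYs ("dominant":
cheaper and more effective). The probabilistic analysis shows how uncertain
these point estimates are:

```sh
$ fitcea psa --n-sims 2000 --seed 2020 --out-dir out
dC 95% CI (-81,157,249; 88,643,768) EUR, dQALY 95% CI (-1,864; 2,854)
```

The credibility intervals on both increments straddle zero by two orders
of magnitude more than the point estimates — the verdict rests on the
CEAC (written to `out/ceac.csv`), which puts the probability of
cost-effectiveness only slightly above one half at conventional
thresholds. Other subcommands: `scenarios` (full scenario and
discount-rate table), `tornado` (ICER percent changes), `synth`
(synthetic-trial demonstration of the transition-estimation path). The
same functionality is available as a library (`fitcea.builtin_fixture`,
`run_deterministic`, `run_psa`, `compute_ceac`, ...).

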