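# Published model-input parameter set for the EuroFIT Markov cohort model.
# Values are transcribed verbatim, including trailing precision (0.0046, not
# 0.005). 'point' is the reported central value; beta/gamma parameters are
# the distributions used in the probabilistic sensitivity analysis. Entries
# marked dist: fixed are literature-sourced and never perturbed.
model:
  cohort_size: 10000
  horizon_years: 5
  cycle_length_years: 1
  discount_rate_costs_annual: 0.035
  discount_rate_effects_annual: 0.035
  effect_duration_years: horizon
  initial_activity_proportions:
    inactive: 0.175
    moderate: 0.105
    recommended: 0.720
activity_transitions:
  eurofit:
    inactive:
      inactive:    {point: 0.18,  dist: beta, alpha: 4.0,   beta: 17.0}
      moderate:    {point: 0.054, dist: beta, alpha: 0.34,  beta: 5.7}
      recommended: {point: 0.71,  dist: beta, alpha: 59.4,  beta: 19.6}
    moderate:
      inactive:    {point: 0.085, dist: beta, alpha: 0.44,  beta: 4.56}
      moderate:    {point: 0.042, dist: beta, alpha: 0.09,  beta: 1.9}
      recommended: {point: 0.82,  dist: beta, alpha: 33.8,  beta: 5.2}
    recommended:
      inactive:    {point: 0.042, dist: beta, alpha: 0.83,  beta: 18.2}
      moderate:    {point: 0.023, dist: beta, alpha: 0.24,  beta: 9.8}
      recommended: {point: 0.89,  dist: beta, alpha: 357.9, beta: 26.1}
  control:
    inactive:
      inactive:    {point: 0.33,  dist: beta, alpha: 11.5,  beta: 21.5}
      moderate:    {point: 0.12,  dist: beta, alpha: 1.6,   beta: 10.4}
      recommended: {point: 0.49,  dist: beta, alpha: 25.0,  beta: 23.0}
    moderate:
      inactive:    {point: 0.19,  dist: beta, alpha: 2.1,   beta: 8.0}
      moderate:    {point: 0.17,  dist: beta, alpha: 1.5,   beta: 6.6}
      recommended: {point: 0.58,  dist: beta, alpha: 16.6,  beta: 10.4}
    recommended:
      inactive:    {point: 0.10,  dist: beta, alpha: 4.2,   beta: 37.8}
      moderate:    {point: 0.064, dist: beta, alpha: 1.9,   beta: 26.1}
      recommended: {point: 0.80,  dist: beta, alpha: 290.7, beta: 58.3}
epidemiology:
  disease_incidence_annual:
    inactive:
      colorectal_cancer: 0.015
      chd: 0.011
      t2d: 0.005
      stroke: 0.0046
      depression: 0.010
    moderate:
      colorectal_cancer: 0.011
      chd: 0.009
      t2d: 0.0038
      stroke: 0.0033
      depression: 0.0094
    recommended:
      colorectal_cancer: 0.0096
      chd: 0.008
      t2d: 0.0033
      stroke: 0.0029
      depression: 0.0092
  activity_mortality_annual:
    inactive: 0.016
    moderate: 0.012
    recommended: 0.010
  disease_mortality_annual:
    colorectal_cancer: 0.092
    chd: 0.002
    t2d: 0.015
    stroke: 0.400
    depression: 0.030
payoffs:
  perspective: societal
  utility_source: trial
  utilities_per_year:
    trial:
      inactive:    {point: 0.909, dist: beta, alpha: 3.0, beta: 0.38}
      moderate:    {point: 0.919, dist: beta, alpha: 5.1, beta: 0.51}
      recommended: {point: 0.922, dist: beta, alpha: 5.1, beta: 0.43}
    literature:
      inactive:    {point: 0.80, dist: fixed}
      moderate:    {point: 0.87, dist: fixed}
      recommended: {point: 0.91, dist: fixed}
    disease:
      colorectal_cancer: {point: 0.786, dist: fixed}
      chd:               {point: 0.735, dist: fixed}
      t2d:               {point: 0.785, dist: fixed}
      stroke:            {point: 0.62,  dist: fixed}
      depression:        {point: 0.57,  dist: fixed}
  annual_costs_eur2017:
    societal:
      inactive:    {point: 2436, dist: gamma, shape: 0.19, scale: 12658}
      moderate:    {point: 1506, dist: gamma, shape: 0.22, scale: 6920}
      recommended: {point: 1997, dist: gamma, shape: 0.24, scale: 8222}
      colorectal_cancer: {point: 34085, dist: fixed}
      chd:               {point: 5239,  dist: fixed}
      t2d:               {point: 5907,  dist: fixed}
      stroke:            {point: 24979, dist: fixed}
      depression:        {point: 6819,  dist: fixed}
    healthcare:
      inactive:    {point: 1107, dist: gamma, shape: 0.10, scale: 10924}
      moderate:    {point: 594,  dist: gamma, shape: 0.35, scale: 1707}
      recommended: {point: 747,  dist: gamma, shape: 0.19, scale: 4040}
      colorectal_cancer: {point: 25346, dist: fixed}
      chd:               {point: 1954,  dist: fixed}
      t2d:               {point: 3089,  dist: fixed}
      stroke:            {point: 18750, dist: fixed}
      depression:        {point: 966,   dist: fixed}
  program_cost_eur: 260
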