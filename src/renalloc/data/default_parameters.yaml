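# Default parameter set: Australian deceased-donor kidney allocation analysis.
#
# Weibull proportional-hazards triples (lam, gamma, beta_age) per allocation
# strategy and transition, fitted at the recipient-age covariate; SEMs feed
# the probabilistic sensitivity analysis (normal draws, truncated positive
# for lam and gamma).  Fixed annual probabilities are shared across
# strategies (beta draws in the PSA).  Costs are 2018 AUD (uniform +/-15% in
# the PSA); utilities are QALY weights (uniform over their 95% CI).
#
# Note on current-practice graft_failure beta_age: the source estimate is
# reported with a positive sign (+0.020).  A positive coefficient of that
# magnitude implies a 36% first-year graft-failure probability at age 50 and
# cohort totals irreconcilable with the published league table, while all
# four allocation subsets carry negative coefficients of similar magnitude
# (-0.013 .. -0.021).  The sign is treated as a misprint and corrected to
# -0.020 here; see docs/methods.md.
currency: AUD 2018
shared:
  fixed_probabilities:
    death_waitlist: {p: 0.0184, sem: 0.0003, distribution: beta}
    death_post_graft_failure: {p: 0.1091, sem: 0.0006, distribution: beta}
  utilities:
    transplant: {value: 0.82, ci_low: 0.74, ci_high: 0.90, distribution: uniform}
    dialysis: {value: 0.70, ci_low: 0.62, ci_high: 0.78, distribution: uniform}
  costs_aud:
    transplant_first_year: {value: 99968.0, rel_range: 0.15, distribution: uniform}
    transplant_subsequent_year: {value: 13916.0, rel_range: 0.15, distribution: uniform}
    dialysis: {value: 81689.34, rel_range: 0.15, distribution: uniform}
options:
  current:
    transplant:
      {lam: 0.2898, gamma: 1.544, beta_age: -0.009,
       sem_lam: 0.0184, sem_gamma: 0.0188, sem_beta: 0.0011}
    graft_failure:
      {lam: 0.1662, gamma: 0.4424, beta_age: -0.020,
       sem_lam: 0.0199, sem_gamma: 0.0158, sem_beta: 0.0025}
    death_post_transplant:
      {lam: 0.0020, gamma: 0.9348, beta_age: 0.0475,
       sem_lam: 0.0004, sem_gamma: 0.0313, sem_beta: 0.0036}
  option_1:
    transplant:
      {lam: 0.2194, gamma: 1.609, beta_age: -0.006,
       sem_lam: 0.0225, sem_gamma: 0.0237, sem_beta: 0.0017}
    graft_failure:
      {lam: 0.2018, gamma: 0.4178, beta_age: -0.021,
       sem_lam: 0.0359, sem_gamma: 0.0180, sem_beta: 0.0034}
    death_post_transplant:
      {lam: 0.0023, gamma: 0.9410, beta_age: 0.0465,
       sem_lam: 0.0007, sem_gamma: 0.0353, sem_beta: 0.0046}
  option_2:
    transplant:
      {lam: 0.3148, gamma: 1.481, beta_age: -0.008,
       sem_lam: 0.0222, sem_gamma: 0.0217, sem_beta: 0.0013}
    graft_failure:
      {lam: 0.1307, gamma: 0.4898, beta_age: -0.019,
       sem_lam: 0.0187, sem_gamma: 0.0212, sem_beta: 0.0031}
    death_post_transplant:
      {lam: 0.0022, gamma: 0.8720, beta_age: 0.0457,
       sem_lam: 0.0006, sem_gamma: 0.0396, sem_beta: 0.0046}
  option_3:
    transplant:
      {lam: 0.3102, gamma: 1.5982, beta_age: -0.011,
       sem_lam: 0.0292, sem_gamma: 0.0235, sem_beta: 0.0016}
    graft_failure:
      {lam: 0.1219, gamma: 0.4081, beta_age: -0.013,
       sem_lam: 0.0232, sem_gamma: 0.0185, sem_beta: 0.0036}
    death_post_transplant:
      {lam: 0.0021, gamma: 0.9407, beta_age: 0.0479,
       sem_lam: 0.0006, sem_gamma: 0.0357, sem_beta: 0.0046}
  option_4:
    transplant:
      {lam: 0.3387, gamma: 1.490, beta_age: -0.010,
       sem_lam: 0.0243, sem_gamma: 0.0227, sem_beta: 0.0014}
    graft_failure:
      {lam: 0.1173, gamma: 0.4536, beta_age: -0.015,
       sem_lam: 0.0179, sem_gamma: 0.0204, sem_beta: 0.0033}
    death_post_transplant:
      {lam: 0.0018, gamma: 0.8841, beta_age: 0.0521,
       sem_lam: 0.0005, sem_gamma: 0.0392, sem_beta: 0.0046}
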