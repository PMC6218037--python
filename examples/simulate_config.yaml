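# Generator configuration for `frailtrans simulate --config`.
# Omitted keys keep their defaults (study-scale cohort: n=2324, 156/254
# enumeration blocks, states 32.7/57.9/9.4%, 20.2% attrition).
n_baseline: 2324
mode: state

# Missing-at-random masking, driven by age (older participants more likely
# missing). Rates are marginal fractions per field.
missing_rates:
  pase_score: 0.06
  grip_left_1: 0.03
  grip_left_2: 0.03
  walk_time_1: 0.03
  walk_time_2: 0.03
  dssi_score: 0.06
  income_monthly: 0.08
missingness_depends_on: [age]

# A binary exposure tilting 12-month transitions: 24.2% prevalence,
# conditional odds ratio exp(1.06) ~ 2.9 on the worsened category.
exposure_effects:
  low_activity_exposure:
    prevalence: 0.242
    log_or: 1.0647
    outcome: worsened
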