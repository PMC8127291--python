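# Base-case inputs for the sarcopenia screening cost-effectiveness model.
# Costs are 2019 USD (converted at the official rate of 42,000 Rial/USD).
# Probabilities and rates are per one-year Markov cycle unless noted.
# Uncertainty: `sd` where a standard deviation is stated, `ci` where a 95%
# confidence interval is stated; parameters with neither receive an SD equal
# to default_sd_fraction of the mean. `family: fixed` excludes a parameter
# from probabilistic sensitivity analysis.

run:
  horizon_cycles: 25        # life-expectancy-based horizon at age 60, years
  cycle_length: 1.0         # years
  cohort_size: 1000         # hypothetical cohort entering the decision tree
  wtp: 5520.311             # USD/QALY, one GDP per capita
  default_sd_fraction: 0.125
  stage2_charge_multiplier: 1.0

conventions:
  half_cycle: trapezoid
  mortality_mode: constant

# Optional age-indexed annual death probabilities for the healthy arm
# (cycle 1 = age 60), used when conventions.mortality_mode is "vector".
# Synthetic approximation of a national period life table for ages 60-84
# (annualized from 5-year abridged-table blocks); the constant scalar above
# is the documented default.
mortality_vector:
  [0.012, 0.012, 0.012, 0.012, 0.012,
   0.018, 0.018, 0.018, 0.018, 0.018,
   0.030, 0.030, 0.030, 0.030, 0.030,
   0.050, 0.050, 0.050, 0.050, 0.050,
   0.085, 0.085, 0.085, 0.085, 0.085]

parameters:
  prevalence: {base: 0.245, sd: 0.08, family: beta}
  discount_rate: {base: 0.05, ci: [0.03, 0.12], family: beta}

  # screening test operating characteristics
  sens_ewgsop: {base: 1.0, family: fixed}   # no uncertainty stated; mean-1 Beta undefined
  sens_sarsamod: {base: 0.806, ci: [0.767, 0.842], family: beta}
  sens_msra: {base: 0.804, sd: 0.08, family: beta}
  sens_sarcf: {base: 0.168, ci: [0.135, 0.206], family: beta}
  spec_ewgsop: {base: 0.84, ci: [0.816, 0.862], family: beta}
  spec_sarsamod: {base: 0.788, ci: [0.75, 0.803], family: beta}
  spec_msra: {base: 0.604, ci: [0.543, 0.664], family: beta}
  spec_sarcf: {base: 0.866, ci: [0.843, 0.886], family: beta}

  # transition probabilities (per cycle)
  p_death_healthy: {base: 0.09, family: beta}      # normal population, 60+ yrs
  p_death_sarc: {base: 0.132, sd: 0.013, family: beta}
  p_death_sarc_cvd: {base: 0.198, sd: 0.03, family: beta}
  p_death_fracture: {base: 0.171, sd: 0.02, family: beta}
  p_fall: {base: 0.273, sd: 0.03, family: beta}
  p_fracture_given_fall: {base: 0.40, sd: 0.05, family: beta}
  p_cvd: {base: 0.27, sd: 0.03, family: beta}

  # costs (USD)
  cost_treatment_annual: {base: 1119.048, sd: 119.047, family: gamma}
  cost_gait: {base: 0.714, family: gamma}
  cost_handgrip: {base: 1.309, family: gamma}
  cost_dxa: {base: 42.857, family: gamma}
  cost_msra: {base: 0.714, family: gamma}
  cost_sarcf: {base: 0.714, family: gamma}
  cost_sarcf_high_risk: {base: 44.880, family: gamma}
  cost_sarsamod: {base: 1.785, family: gamma}
  cost_ewgsop_stage1: {base: 2.023, family: gamma}   # gait speed + handgrip
  cost_ewgsop_stage2: {base: 42.857, family: gamma}  # DXA confirmation
  cost_fracture: {base: 3599.048, sd: 695.074, family: gamma}
  cost_cvd_initial: {base: 4149.286, family: gamma}
  cost_cvd_incremental: {base: 1904.762, sd: 190.476, family: gamma}

  # health-state utilities
  u_healthy: {base: 0.76, family: beta}
  u_sarc: {base: 0.68, family: beta}
  u_sarc_fracture: {base: 0.51, family: beta}
  u_sarc_cvd: {base: 0.56, family: beta}
  u_sarc_cvd_fracture: {base: 0.42, family: beta}

  # intervention efficacy (vitamin D, supplements, exercise, diet)
  efficacy: {base: 0.40, sd: 0.15, family: beta}
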