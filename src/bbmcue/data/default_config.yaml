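# Base-case model inputs (2022 euros). Loading this file is equivalent to
# the built-in defaults; edit a copy to run scenarios.
schema: 1
dialect: text   # amyloid prevalence dialect: "text" (0.548/0.841) or "table1" (0.555/0.84)

econ:
  start_age: 65
  horizon: 30
  cycle_length: 1
  discount_rate_costs: 0.03
  discount_rate_effects: 0.03
  wtp: 50000
  half_cycle_correction: false

population:
  share_scd: 0.53
  share_mci: 0.30
  share_mild_dem: 0.17
  amyloid_prev_scd: 0.31
  # amyloid_prev_mci / amyloid_prev_dem follow the dialect unless set here

accuracy:
  bbm_sensitivity: 0.89
  bbm_specificity: 0.69
  csf_sensitivity: 0.91
  csf_specificity: 0.89

policy:
  soc_referral_rate: 0.52
  bbm_positive_referral_rate: 1.0

natural_history:
  p_scd_to_mci_amypos: 0.41
  p_mci_to_mild_amypos: 0.22
  p_scd_to_mci_amyneg: 0.10
  p_mci_to_mild_amyneg: 0.05
  progression_odds_ratio: 5.89

treatment:
  effect: 0.27
  max_duration: 2
  annual_cost: 5000
  responder_fraction_amypos: 1.0
  responder_fraction_amyneg: 0.0

costs:
  phc_cost_scd: 959
  phc_cost_mci: 1896
  phc_cost_dem: 1896
  csf_exam_incl_mc_visit: 1940
  mc_visit: 524
  bbm_test: 200
  state_cost_scd_mci: 9180
  state_cost_mild: 27014
  state_cost_moderate: 30824
  state_cost_severe: 35471
  state_cost_mild_ltc: 81383
  state_cost_moderate_ltc: 66849
  state_cost_severe_ltc: 66977

utilities:
  u_scd_amyneg: 0.87
  u_scd_amypos: 0.86
  u_mci_amyneg: 0.71
  u_mci_amypos: 0.81
  u_mild: 0.74
  u_moderate: 0.59
  u_severe: 0.36
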