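# Trial scenario: survival in *both* arms comes directly from trial
# follow-up (per-arm transition blocks below); no control-arm derivation is
# needed.  Trastuzumab costs are partly trial-based (number of
# administrations) and partly cohort-based (vial use, unit prices); other
# resource use and utilities remain the cohort estimates.
#
# The trial's published survival tables are not reprinted in the source, so
# the per-arm probabilities below are placeholders with the structural
# property that defines this scenario: the disease-free-survival event
# probability never exceeds the distant-metastasis event probability, hence
# the local-recurrence state is never entered and carries no cost.
scenario: trial
start_age: 55
discount_costs: 0.04
discount_effects: 0.015
wtp: 80000
benefit_duration: 8

hazard_ratios:           # used only for the cardiac relative risk here
  dfs: {mean: 0.76, family: fixed}
  os: {mean: 0.76, family: fixed}
  dm: {mean: 0.50, family: fixed}
  cardiac_rr: {mean: 5.3, family: fixed}
  dm_after_lr: {mean: 1.0, family: fixed}

transitions:
  trastuzumab:
    death_overall:
      first_year: {mean: 0.002, se: 0.001, family: beta}
      subsequent: {mean: 0.018, se: 0.004, family: beta}
    dfs_event:
      first_year: {mean: 0.020, se: 0.005, family: beta}
      subsequent: {mean: 0.038, se: 0.006, family: beta}
    dm_event:
      first_year: {mean: 0.025, se: 0.005, family: beta}
      subsequent: {mean: 0.048, se: 0.007, family: beta}
    cardiac_first_year: {mean: 0.030, se: 0.010, family: beta}
  control:               # treated-arm hazards divided by the hazard ratios
    death_overall:
      first_year: {mean: 0.0026, se: 0.001, family: beta}
      subsequent: {mean: 0.0236, se: 0.005, family: beta}
    dfs_event:
      first_year: {mean: 0.0262, se: 0.006, family: beta}
      subsequent: {mean: 0.0497, se: 0.007, family: beta}
    dm_event:
      first_year: {mean: 0.0494, se: 0.008, family: beta}
      subsequent: {mean: 0.0937, se: 0.010, family: beta}

state_costs:
  dfs:
    first_year: {mean: 12776, se: 798.14, family: gamma}
    subsequent: {mean: 1237, se: 107.49, family: gamma}
  lr:
    first_year: {mean: 12777, se: 2203.85, family: gamma}
    subsequent: {mean: 14149, se: 4679.22, family: gamma}
  dm:
    first_year: {mean: 30165, se: 2339.46, family: gamma}
    subsequent: {mean: 47959, se: 13877.79, family: gamma}

cardiac_monitoring_cost: {mean: 467, se: 18.90, family: gamma}

trastuzumab:
  vials_per_cycle: {mean: 3, se: 0.050, family: gamma}
  n_administrations: {mean: 18, se: 0.420, family: gamma}  # 3-weekly over 1 year
  vial_price: {mean: 605, family: fixed}
  admin_price: {mean: 257, family: fixed}
  her2_testing: {mean: 0, family: fixed}

utilities:
  dfs:
    first_year: {mean: 0.728, se: 0.020, family: beta}
    subsequent: {mean: 0.80, se: 0.020, family: beta}
  lr:
    first_year: {mean: 0.71, se: 0.030, family: beta}
    subsequent: {mean: 0.71, se: 0.030, family: beta}
  dm:
    first_year: {mean: 0.60, se: 0.030, family: beta}
    subsequent: {mean: 0.60, se: 0.030, family: beta}
cardiac_disutility: {mean: 0.128, family: fixed}

life_table: life_table_synthetic.csv
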