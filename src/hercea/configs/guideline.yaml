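# Guideline scenario: as real_world, but transition probabilities and
# trastuzumab costs come from the subgroup of patients treated in full
# concordance with the 2005 clinical guideline.  The subgroup's transition
# table is not printed in the source; the values below are placeholders
# chosen close to the full-cohort figures (slightly better survival, a
# slightly higher number of administrations), to be replaced with subgroup
# estimates for substantive use.
scenario: guideline
start_age: 55
discount_costs: 0.04
discount_effects: 0.015
wtp: 80000
benefit_duration: 8

hazard_ratios:
  dfs: {mean: 0.76, family: fixed}
  os: {mean: 0.76, family: fixed}
  dm: {mean: 0.50, family: fixed}
  cardiac_rr: {mean: 5.3, family: fixed}
  dm_after_lr: {mean: 1.0, family: fixed}

transitions:             # guideline-subgroup placeholders
  death_overall:
    first_year: {mean: 0.000, family: fixed}
    subsequent: {mean: 0.024, se: 0.006, family: beta}
  dfs_event:
    first_year: {mean: 0.014, se: 0.028, family: beta}
    subsequent: {mean: 0.048, se: 0.060, family: beta}
  dm_event:
    first_year: {mean: 0.003, se: 0.002, family: beta}
    subsequent: {mean: 0.036, se: 0.006, family: beta}
  cardiac_first_year: {mean: 0.125, se: 0.030, family: beta}

state_costs:             # shared cohort estimates, treatment-independent
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
  n_administrations: {mean: 15.14, se: 0.420, family: gamma}
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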