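# Real-world scenario: annual transition probabilities and trastuzumab costs
# observed in the full trastuzumab-treated cohort; the control arm is derived
# by dividing the treated arm's hazards by the trial hazard ratios.
#
# Every numeric leaf is either fixed (bare number / se 0) or a
# {mean, se, family} distribution used by the probabilistic analysis.
# Monetary values are 2012 euros.
#
# Leaves marked "placeholder" stand in for inputs the source tables do not
# print (the trial hazard ratios and several utilities/uncertainties); they
# are plausible values for demonstration and testing, not cohort estimates,
# and should be replaced for any substantive analysis.
scenario: real_world
start_age: 55            # cohort mean age at diagnosis, years (placeholder)
discount_costs: 0.04     # per year, Dutch pharmacoeconomic guideline
discount_effects: 0.015
wtp: 80000               # euros per QALY, high-burden-disease threshold
benefit_duration: 8      # years the trial hazard ratios apply

hazard_ratios:           # trastuzumab vs control; trial estimates (placeholder)
  dfs: {mean: 0.76, family: fixed}
  os: {mean: 0.76, family: fixed}
  dm: {mean: 0.50, family: fixed}
  cardiac_rr: {mean: 5.3, family: fixed}   # relative risk, cardiac toxicity
  dm_after_lr: {mean: 1.0, family: fixed}  # extra DM hazard after local recurrence

transitions:             # treated-arm composite annual probabilities
  death_overall:         # 1 - overall survival
    first_year: {mean: 0.000, family: fixed}
    subsequent: {mean: 0.026, se: 0.006, family: beta}
  dfs_event:             # 1 - disease-free survival
    first_year: {mean: 0.016, se: 0.031, family: beta}
    subsequent: {mean: 0.054, se: 0.067, family: beta}
  dm_event:              # 1 - distant-metastasis-free survival
    first_year: {mean: 0.003, se: 0.002, family: beta}
    subsequent: {mean: 0.041, se: 0.006, family: beta}
  cardiac_first_year: {mean: 0.125, se: 0.030, family: beta}  # severe cardiac events, year 1

state_costs:             # euros per year in state, treatment-independent
  dfs:
    first_year: {mean: 12776, se: 798.14, family: gamma}
    subsequent: {mean: 1237, se: 107.49, family: gamma}
  lr:
    first_year: {mean: 12777, se: 2203.85, family: gamma}
    subsequent: {mean: 14149, se: 4679.22, family: gamma}
  dm:
    first_year: {mean: 30165, se: 2339.46, family: gamma}
    subsequent: {mean: 47959, se: 13877.79, family: gamma}

cardiac_monitoring_cost: {mean: 467, se: 18.90, family: gamma}  # per treated patient, year 1

trastuzumab:             # acquisition-cost inputs, treated arm, cycle 1
  vials_per_cycle: {mean: 3, se: 0.050, family: gamma}
  n_administrations: {mean: 15, se: 0.420, family: gamma}
  vial_price: {mean: 605, family: fixed}       # per 150 mg vial
  admin_price: {mean: 257, family: fixed}      # day-care administration
  her2_testing: {mean: 0, family: fixed}       # IHC/FISH; no printed unit price

utilities:               # EQ-5D (UK tariff) weights; non-DFS values placeholder
  dfs:
    first_year: {mean: 0.728, se: 0.020, family: beta}
    subsequent: {mean: 0.80, se: 0.020, family: beta}
  lr:
    first_year: {mean: 0.71, se: 0.030, family: beta}
    subsequent: {mean: 0.71, se: 0.030, family: beta}
  dm:
    first_year: {mean: 0.60, se: 0.030, family: beta}
    subsequent: {mean: 0.60, se: 0.030, family: beta}
cardiac_disutility: {mean: 0.128, family: fixed}  # 0.728 - 0.600, one cycle

life_table: life_table_synthetic.csv
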