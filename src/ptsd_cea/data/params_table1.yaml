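# Model input parameters: point estimates, deterministic sensitivity ranges
# (in parentheses in the source schedule; absent ranges default to +/-30%),
# and Beta/Gamma uncertainty distributions for the probabilistic analysis.
# Costs are unit fees in 2010/2011 Australian dollars.
currency: "A$ 2010/2011"

effectiveness:
  # probability of no longer meeting full PTSD diagnostic criteria at the
  # end of the 12-week course (response, including remission of co-morbid
  # depression in responders)
  p_response_tfcbt:        {point: 0.42, low: 0.29, high: 0.55, beta: [24.3, 33.6]}
  p_response_tfcbt_ssri:   {point: 0.44, low: 0.31, high: 0.57, beta: [23.5, 29.9]}
  p_response_counselling:  {point: 0.34, low: 0.24, high: 0.44, beta: [27.8, 54.0]}
  # 12-month probability of recovery from a depressive episode on
  # second-line sertraline (compliant fraction folded in)
  p_ssri_depression:       {point: 0.60, low: 0.42, high: 0.78, beta: [16.5, 11.0]}

pathways:
  p_comorbid_depression:   {point: 0.58, low: 0.40, high: 0.75}
  p_delayed_response:      {point: 0.17, low: 0.12, high: 0.22, beta: [35.3, 172.1]}
  p_spont_remit_year1:     {point: 0.17, low: 0.12, high: 0.22, beta: [35.3, 172.1]}
  # 12-month probabilities, converted to per-cycle inside the engine
  p_dep_spont_remission:   {point: 0.53, low: 0.37, high: 0.69, beta: [19.5, 17.3]}
  p_dep_recurrence:        {point: 0.14, low: 0.09, high: 0.18, beta: [36.6, 224.6]}
  ssri_continuation_months: 9
  # per-cycle probability of spontaneous recovery from PTSD among year-1
  # non-remitters, by years since baseline (bands tile years 2-29)
  ptsd_recovery_schedule:
    - {years: [2, 2],   per_cycle: 0.0083}
    - {years: [3, 4],   per_cycle: 0.0041}
    - {years: [5, 6],   per_cycle: 0.0021}
    - {years: [7, 8],   per_cycle: 0.0043}
    - {years: [9, 11],  per_cycle: 0.0035}
    - {years: [12, 13], per_cycle: 0.0023}
    - {years: [14, 16], per_cycle: 0.0013}
    - {years: [17, 20], per_cycle: 0.0028}
    - {years: [21, 29], per_cycle: 0.0020}

mortality:
  # per 3-month cycle, by attained-age band
  age_bands: [[10, 14], [15, 19], [20, 29], [30, 40]]
  suicide:
    general:   [0.0, 0.0000155, 0.0000316, 0.0000387]
    ptsd_dep:  [0.0, 0.000334,  0.000343,  0.000744]
    dep_only:  [0.0, 0.000186,  0.000379,  0.000465]
    ptsd_only: [0.0, 0.000032,  0.000066,  0.000080]
  other_cause: [0.000027, 0.000070, 0.000104, 0.000169]

costs:
  sertraline_month:        {point: 24.66,  gamma: [96.04, 3.89]}
  psychologist_first:      {point: 140.90, gamma: [96.04, 0.68]}
  psychologist_subsequent: {point: 96.00,  gamma: [96.04, 1.00]}
  psychiatrist_first:      {point: 250.45, gamma: [96.04, 0.38]}
  psychiatrist_subsequent: {point: 125.80, gamma: [96.04, 0.76]}
  gp_consult:              {point: 66.00,  gamma: [96.04, 1.46]}
  parent_component:        {point: 58.85,  gamma: [96.04, 1.63]}

utilities:
  # population norms (not varied in sensitivity analysis)
  u_well_10_30: {point: 0.87}
  u_well_30_40: {point: 0.85}
  # disease-state utilities (AQoL-4D)
  u_ptsd:     {point: 0.61, low: 0.43, high: 0.79, gamma: [96.04,  157.4]}
  u_ptsd_dep: {point: 0.53, low: 0.37, high: 0.69, gamma: [96.044, 181.21]}
  u_dep:      {point: 0.46, low: 0.32, high: 0.60, gamma: [96.044, 208.78]}

settings:
  discount_rate_annual: 0.05
  cycle_length_months: 3
  tree_horizon_months: 12
  markov_horizon_years: 30
  baseline_age_years: 10
  psa_trials: 1000
  rng_seed: 0
  discount_year1: false
  ssri_compliance: 1.0
  recurrence_over_horizon: true
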