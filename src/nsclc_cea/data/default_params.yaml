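weibull:
  pfs_control:
    scale: 0.1559
    shape: 1.045
    adj_r2: 0.976
    time_unit: cycle
  os_supportive:
    scale: 0.04006
    shape: 1.156
    adj_r2: 0.9898
    time_unit: cycle
  os_secondline:
    scale: 0.03897
    shape: 1.509
    adj_r2: 0.981
    time_unit: cycle
params:
  hr_pfs_gefitinib_egfr_pos:
    base: 0.17
    low: 0.07
    high: 0.42
    distribution: lognormal_from_ci
    units: ''
  egfr_mutation_freq:
    base: 0.5
    low: 0.08
    high: 0.7
    distribution: beta
    units: ''
  p_secondline:
    base: 0.566
    low: 0.26
    high: 0.72
    distribution: beta
    units: ''
  p_sae_gefitinib:
    base: 0.07
    low: 0.0525
    high: 0.0875
    distribution: beta
    units: ''
  p_sae_control:
    base: 0.03
    low: 0.0225
    high: 0.0375
    distribution: beta
    units: ''
  p_sae_platinum:
    base: 0.8
    low: 0.6
    high: 1.0
    distribution: beta
    units: ''
  cost_genotyping:
    base: 507.9
    low: 381.0
    high: 634.9
    distribution: lognormal
    units: USD, one-time
  cost_gefitinib_250mg:
    base: 77.8
    low: 38.9
    high: 77.8
    distribution: lognormal
    units: USD per 250 mg dose
  cost_followup_visit:
    base: 55.6
    low: 41.7
    high: 69.4
    distribution: lognormal
    units: USD per visit
  cost_secondline_cycle:
    base: 2352.7
    low: 1921.1
    high: 4383.3
    distribution: lognormal
    units: USD per cycle
  cost_endoflife:
    base: 3664.3
    low: 21.4
    high: 48750.2
    distribution: lognormal
    units: USD, one-time
  cost_supportive_cycle:
    base: 337.5
    low: 158.7
    high: 793.7
    distribution: lognormal
    units: USD per cycle
  cost_sae_platinum_cycle:
    base: 507.4
    low: 189.7
    high: 825.0
    distribution: lognormal
    units: USD per cycle
  utility_pfs:
    base: 0.65
    low: 0.26
    high: 0.87
    distribution: beta
    units: ''
  utility_pd:
    base: 0.47
    low: 0.19
    high: 0.58
    distribution: beta
    units: ''
settings:
  cycle_days: 21.0
  horizon_years: 10.0
  discount_annual: 0.03
  followup_interval_early_months: 4.0
  followup_interval_late_months: 12.0
  followup_switch_years: 2.0
  secondline_cycles: 4
  gpap_enabled: false
  gpap_paid_months: 6.0
  wtp_thresholds:
  - 16349.1
  - 38733.3
  half_cycle_correction: false
  followup_all_states: true
  discount_life_years: false
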