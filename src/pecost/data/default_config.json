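{
  "probabilities": {
    "p_hosp_no_test": 0.14444444444444443,
    "share_low": 0.7944444444444444,
    "share_high": 0.20555555555555557,
    "p_hosp_given_low": 0.0056,
    "p_hosp_given_high": 0.4
  },
  "costs": {
    "outpatient": 57053.0,
    "hosp_per_day": 87300.0,
    "test_cost": 9000.0,
    "corticosteroid": 1752.0,
    "nicu_per_day": 101302.0
  },
  "stays": {
    "pre_onset_days": 4.0,
    "birth_pe_days": 13.6,
    "birth_no_pe_days": 9.3,
    "avg_los_no_test": 10.4,
    "avg_los_test": 10.2,
    "nicu_days": null
  },
  "neonatal": {
    "rds_rate": 0.12,
    "rds_reduction": 0.2
  },
  "cohort": {
    "n_model": 31000,
    "n_sample": 180,
    "n_enrolled": 192
  },
  "performance": {
    "cutoff": 38.0,
    "npv_1wk": 0.986,
    "npv_4wk": 0.951,
    "ppv_1wk": 0.179,
    "ppv_4wk": 0.303
  },
  "pe_incidence": 0.10121111111111111,
  "target_budget_impact": 507560536.0
}
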