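{
  "schema_version": 1,
  "covariate_baselines": {
    "waist_cm": {"mean": 92.0, "sd": 16.0},
    "sbp_mmhg": {"mean": 118.0, "sd": 14.0},
    "dbp_mmhg": {"mean": 73.7, "sd": 10.0},
    "tg_mmol_l": {"mean": 1.4, "sd": 1.0},
    "hdl_mmol_l": {"mean": 1.45, "sd": 0.45},
    "glucose_mmol_l": {"mean": 5.2, "sd": 0.9},
    "insulin_pmol_l": {"mean": 99.0, "sd": 67.0}
  },
  "covariate_effects": {
    "waist_cm": 0.55,
    "sbp_mmhg": 0.36,
    "dbp_mmhg": 0.4,
    "tg_mmol_l": 0.32,
    "hdl_mmol_l": -0.27,
    "glucose_mmol_l": 0.2,
    "insulin_pmol_l": 0.29
  },
  "presets": {
    "development": {
      "n": 1040,
      "age_mean": 45.4,
      "age_sd": 14.2,
      "age_range": [18.0, 72.0],
      "sex_ratio_female": 0.515,
      "bmi_mean": 27.7,
      "bmi_sd": 5.3,
      "latent_effect": 0.8,
      "target_prevalence_low": 0.59,
      "misreporter_fraction": 0.0
    },
    "external": {
      "n": 3344,
      "age_mean": 66.5,
      "age_sd": 6.4,
      "age_range": [47.0, 91.0],
      "sex_ratio_female": 0.483,
      "bmi_mean": 27.1,
      "bmi_sd": 4.8,
      "latent_effect": 0.8,
      "target_prevalence_low": 0.55,
      "misreporter_fraction": 0.25
    }
  }
}
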