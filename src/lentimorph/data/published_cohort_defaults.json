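{
  "description": "Default cohort configuration: three groups (MSA-P, PD, CG, n=19 each) whose index distributions reproduce the published group means and SDs. The smaller-SL side is drawn from N(csl_mean, csl_sd); asymmetry_delta = 2*(SL mean - cSL mean) is the expected left-right |SL| gap, so the side-mean SL recovers the published SL row. The larger-SIsd side is drawn from N(csisd_mean, csisd_sd) with sisd_asymmetry_delta = 2*(cSIsd mean - SIsd mean) analogously.",
  "groups": [
    {
      "label": "MSA-P",
      "n_subjects": 19,
      "asymmetry_delta": 1.7,
      "ll_mean": 14.97,
      "ll_sd": 2.85,
      "area_mean": 146.78,
      "area_sd": 49.3,
      "sim_ln_mean": 698.13,
      "sim_ln_sd": 434.11,
      "sisd_asymmetry_delta": 54.2,
      "sim_csf_mean": 1066.31,
      "sim_csf_sd": 90.53,
      "sisd_csf_mean": 49.02,
      "sisd_csf_sd": 27.27,
      "csl_mean": 4.22,
      "csl_sd": 1.7,
      "csisd_mean": 191.23,
      "csisd_sd": 104.28
    },
    {
      "label": "PD",
      "n_subjects": 19,
      "asymmetry_delta": 1.06,
      "ll_mean": 16.54,
      "ll_sd": 1.66,
      "area_mean": 177.38,
      "area_sd": 28.31,
      "sim_ln_mean": 801.21,
      "sim_ln_sd": 397.56,
      "sisd_asymmetry_delta": 18.1,
      "sim_csf_mean": 1089.97,
      "sim_csf_sd": 86.48,
      "sisd_csf_mean": 51.39,
      "sisd_csf_sd": 27.54,
      "csl_mean": 7.04,
      "csl_sd": 1.76,
      "csisd_mean": 105.65,
      "csisd_sd": 64.64
    },
    {
      "label": "CG",
      "n_subjects": 19,
      "asymmetry_delta": 0.96,
      "ll_mean": 16.86,
      "ll_sd": 1.61,
      "area_mean": 193.42,
      "area_sd": 40.23,
      "sim_ln_mean": 1048.25,
      "sim_ln_sd": 410.81,
      "sisd_asymmetry_delta": 21.76,
      "sim_csf_mean": 1118.57,
      "sim_csf_sd": 100.1,
      "sisd_csf_mean": 66.23,
      "sisd_csf_sd": 33.24,
      "csl_mean": 6.81,
      "csl_sd": 2.16,
      "csisd_mean": 155.97,
      "csisd_sd": 78.37
    }
  ],
  "rater_noise": {
    "sd_length": 0.5,
    "sd_intensity": 25.0,
    "sd_area": 12.0
  }
}
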