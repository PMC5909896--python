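{
  "intercept_ms": 2680.88,
  "coef_age_ms_per_year": 6.36,
  "coef_edu_ms_per_year": -33.56,
  "coef_cuse_ms_per_point": -53.07,
  "residual_sd_ms": 491.94,
  "provenance": "Exp1a printed equation; residual SD derived as 520*sqrt(1-0.105)",
  "r_squared": 0.105
}
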