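{
  "comment": "Simulator response-time calibration: lognormal RT with these defaults yields a mean RT near 1.8 s and ~10% of responses later than the SOA at equilibrium SOAs around 2.3 s.",
  "rt_median_ms": 1800.0,
  "rt_log_sd": 0.20,
  "rt_soa_coupling": 0.0,
  "miss_dominance": 0.87,
  "default_slope": 8.0,
  "default_lapse": 0.02,
  "equilibrium_noise_sd_ms": 480.0,
  "exp1a_ability_intercept_ms": 130.0
}
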