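{
  "W_s": 0.023,
  "V_s": 0.00024,
  "V_ads0": 1e-08,
  "V_h": 3.82,
  "V_b0": 20.0,
  "k_v": 0.00335,
  "n_s0": 1.6e-07,
  "n_ads0": 0.0,
  "n_b0": 0.0,
  "H_Lf": 0.00015,
  "beta_sl": 2997.625,
  "beta_ll": 0.60261,
  "stirred": true,
  "label": "batch2"
}
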