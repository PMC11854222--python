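{
  "W_s": 0.025,
  "V_s": 0.00024,
  "V_ads0": 1e-08,
  "V_h": 3.82,
  "V_b0": 40.0,
  "k_v": 0.00335,
  "n_s0": 1.6e-07,
  "n_ads0": 0.0,
  "n_b0": 0.0,
  "H_Lf": 0.00013,
  "beta_sl": 2889.625,
  "beta_ll": 1.01277,
  "stirred": true,
  "label": "batch1"
}
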