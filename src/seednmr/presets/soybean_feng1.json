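{
  "name": "soybean_feng1",
  "classes": {
    "seed": {
      "ocr_mean_pct": 17.5,
      "ocr_sd_pct": 2.0,
      "weight_mean_g": 0.475,
      "weight_sd_g": 0.06,
      "fraction": 1.0
    }
  },
  "wcr_mean_pct": 10.0,
  "wcr_sd_pct": 1.0
}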