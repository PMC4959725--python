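{
  "name": "soybean_feng2",
  "classes": {
    "seed": {
      "ocr_mean_pct": 20.4,
      "ocr_sd_pct": 1.0,
      "weight_mean_g": 0.21,
      "weight_sd_g": 0.04,
      "fraction": 1.0
    }
  },
  "wcr_mean_pct": 10.0,
  "wcr_sd_pct": 1.0
}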