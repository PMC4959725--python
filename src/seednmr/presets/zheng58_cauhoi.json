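{
  "name": "zheng58_cauhoi",
  "classes": {
    "diploid_reference": {
      "ocr_mean_pct": 6.7,
      "ocr_sd_pct": 0.2,
      "weight_mean_g": 0.42,
      "weight_sd_g": 0.02,
      "fraction": 1.0
    }
  },
  "wcr_mean_pct": 10.0,
  "wcr_sd_pct": 1.0
}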