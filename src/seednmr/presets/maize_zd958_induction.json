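{
  "name": "maize_zd958_induction",
  "classes": {
    "haploid": {
      "ocr_mean_pct": 3.6,
      "ocr_sd_pct": 0.47,
      "weight_mean_g": 0.4,
      "weight_sd_g": 0.049,
      "fraction": 0.0858
    },
    "diploid": {
      "ocr_mean_pct": 5.5,
      "ocr_sd_pct": 0.52,
      "weight_mean_g": 0.43,
      "weight_sd_g": 0.035,
      "fraction": 0.9142
    }
  },
  "wcr_mean_pct": 10.0,
  "wcr_sd_pct": 1.0
}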