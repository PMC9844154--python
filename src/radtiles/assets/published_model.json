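{
  "model": "predicted-TILes linear model",
  "version": 1,
  "coefficients": {
    "glszm_GrayLevelVariance": 0.00171,
    "glszm_LargeAreaLowGrayLevelEmphasis": -2.48e-05
  },
  "intercept": null,
  "intercept_known": false,
  "lambda": null,
  "alpha": 1.0,
  "standardization": {},
  "notes": "Two-feature GLSZM model of TIL enrichment; the intercept was never published, so scores are defined up to an additive constant. Coefficients are treated as original-scale."
}
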