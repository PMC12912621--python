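{
  "schema_version": "1.0",
  "description": "Published adjusted-GMI coefficients: aGMI = beta0 + beta1*GMI + beta2*prior_discordance + beta3*last_hba1c (all HbA1c-scale %, glucose in mg/dL via GMI).",
  "beta0": -0.447,
  "beta1": 0.913,
  "beta2": 0.519,
  "beta3": 0.148
}
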