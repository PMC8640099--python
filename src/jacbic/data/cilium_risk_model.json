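{
 "gene_coefficients": {
  "LRGUK": 0.49,
  "NSUN7": 0.49,
  "LRRC27": -1.50,
  "SPAG17": 0.25,
  "EFHB": -0.31,
  "IFT27": -0.87,
  "DZIP1L": 0.68,
  "FOLR1": 0.33,
  "RGS22": 0.31,
  "TEX9": -0.15,
  "GALNT3": 0.46,
  "GLB1L": 0.84
 },
 "covariate_terms": {},
 "alpha": 1.0,
 "lambda": null
}
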