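{
  "name": "rh2_two_term",
  "intercept": 475.628,
  "terms": [
    ["torsion15_median", -8.720],
    ["rmsf_auc", 34.925]
  ]
}
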