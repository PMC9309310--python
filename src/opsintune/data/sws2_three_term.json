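{
  "name": "sws2_three_term",
  "intercept": 2677.5348,
  "terms": [
    ["angle3_median", -17.052],
    ["torsion3_median", 5.1634],
    ["torsion12_median", 2.3642]
  ]
}
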