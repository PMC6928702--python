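{
 "metrics": {
  "accuracy": 0.8167860798362334,
  "fn": 5,
  "fp": 174,
  "n_excluded": 123,
  "precision": 0.7843866171003717,
  "sensitivity": 0.9921630094043887,
  "specificity": 0.48672566371681414,
  "tn": 165,
  "tp": 633
 },
 "n_bouts": 3,
 "rate_hz": 10.0,
 "tolerance_s": 2.0
}
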