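{
 "metrics": {
  "accuracy": 0.9948822927328557,
  "fn": 5,
  "fp": 0,
  "n_excluded": 123,
  "precision": 1.0,
  "sensitivity": 0.9921630094043887,
  "specificity": 1.0,
  "tn": 339,
  "tp": 633
 },
 "n_bouts": 2,
 "rate_hz": 10.0,
 "tolerance_s": 2.0
}
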