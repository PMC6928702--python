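{
 "comparison": {
  "alpha": 0.05,
  "equal_var": true,
  "normality_p": [
   0.6737906262342497,
   0.6737906262342497
  ],
  "p_value": 1.0,
  "significant": false,
  "test_used": "t_test",
  "variance_p": 0.9999999999999998
 },
 "indiv": {
  "kurtosis": 2.629880899707242,
  "maximum": 1.302356,
  "mean": 1.1933082222222222,
  "median": 1.200241,
  "minimum": 1.071565,
  "n": 63,
  "q1": 1.1577600000000001,
  "q3": 1.228879,
  "sd": 0.05182184643703242,
  "skewness": -0.25201127399831036
 },
 "init": {
  "kurtosis": 2.629880899707242,
  "maximum": 1.302356,
  "mean": 1.1933082222222222,
  "median": 1.200241,
  "minimum": 1.071565,
  "n": 63,
  "q1": 1.1577600000000001,
  "q3": 1.228879,
  "sd": 0.05182184643703242,
  "skewness": -0.25201127399831036
 }
}
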