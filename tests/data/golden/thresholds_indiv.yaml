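metadata:
  subject_id: golden
  th2_left: 0.9299999999999802
  th2_right: 0.9299999999999802
  th3_left: 1.269999999999973
  th3_right: 1.309999999999972
mode: indiv
th1_left: 170.4781156407644
th1_right: 165.4899778312564
th2: 0.9299999999999802
th3: 1.309999999999972
th4: 0.6799999999999855
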