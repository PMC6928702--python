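speed
1.071565
1.230254
1.151733
1.243465
1.158122
1.183035
1.173493
1.156079
1.202524
1.285224
1.137582
1.222338
1.163898
1.190772
1.249240
1.200241
1.295074
1.108844
1.092176
1.180744
1.212520
1.260118
1.157398
1.194637
1.140505
1.254565
1.253875
1.213922
1.192824
1.194942
1.136503
1.102666
1.247373
1.224649
1.217735
1.157247
1.131230
1.203300
1.222021
1.183722
1.217274
1.164943
1.127020
1.152889
1.108006
1.302356
1.238570
1.209660
1.219154
1.233955
1.260823
1.201720
1.245931
1.213597
1.227504
1.167884
1.161541
1.242870
1.213491
1.186073
1.239296
1.160687
1.085019
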