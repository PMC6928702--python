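method,speed,cum_fraction
init,1.071565,0.015873
init,1.085019,0.031746
init,1.092176,0.047619
init,1.102666,0.063492
init,1.108006,0.079365
init,1.108844,0.095238
init,1.127020,0.111111
init,1.131230,0.126984
init,1.136503,0.142857
init,1.137582,0.158730
init,1.140505,0.174603
init,1.151733,0.190476
init,1.152889,0.206349
init,1.156079,0.222222
init,1.157247,0.238095
init,1.157398,0.253968
init,1.158122,0.269841
init,1.160687,0.285714
init,1.161541,0.301587
init,1.163898,0.317460
init,1.164943,0.333333
init,1.167884,0.349206
init,1.173493,0.365079
init,1.180744,0.380952
init,1.183035,0.396825
init,1.183722,0.412698
init,1.186073,0.428571
init,1.190772,0.444444
init,1.192824,0.460317
init,1.194637,0.476190
init,1.194942,0.492063
init,1.200241,0.507937
init,1.201720,0.523810
init,1.202524,0.539683
init,1.203300,0.555556
init,1.209660,0.571429
init,1.212520,0.587302
init,1.213491,0.603175
init,1.213597,0.619048
init,1.213922,0.634921
init,1.217274,0.650794
init,1.217735,0.666667
init,1.219154,0.682540
init,1.222021,0.698413
init,1.222338,0.714286
init,1.224649,0.730159
init,1.227504,0.746032
init,1.230254,0.761905
init,1.233955,0.777778
init,1.238570,0.793651
init,1.239296,0.809524
init,1.242870,0.825397
init,1.243465,0.841270
init,1.245931,0.857143
init,1.247373,0.873016
init,1.249240,0.888889
init,1.253875,0.904762
init,1.254565,0.920635
init,1.260118,0.936508
init,1.260823,0.952381
init,1.285224,0.968254
init,1.295074,0.984127
init,1.302356,1.000000
indiv,1.071565,0.015873
indiv,1.085019,0.031746
indiv,1.092176,0.047619
indiv,1.102666,0.063492
indiv,1.108006,0.079365
indiv,1.108844,0.095238
indiv,1.127020,0.111111
indiv,1.131230,0.126984
indiv,1.136503,0.142857
indiv,1.137582,0.158730
indiv,1.140505,0.174603
indiv,1.151733,0.190476
indiv,1.152889,0.206349
indiv,1.156079,0.222222
indiv,1.157247,0.238095
indiv,1.157398,0.253968
indiv,1.158122,0.269841
indiv,1.160687,0.285714
indiv,1.161541,0.301587
indiv,1.163898,0.317460
indiv,1.164943,0.333333
indiv,1.167884,0.349206
indiv,1.173493,0.365079
indiv,1.180744,0.380952
indiv,1.183035,0.396825
indiv,1.183722,0.412698
indiv,1.186073,0.428571
indiv,1.190772,0.444444
indiv,1.192824,0.460317
indiv,1.194637,0.476190
indiv,1.194942,0.492063
indiv,1.200241,0.507937
indiv,1.201720,0.523810
indiv,1.202524,0.539683
indiv,1.203300,0.555556
indiv,1.209660,0.571429
indiv,1.212520,0.587302
indiv,1.213491,0.603175
indiv,1.213597,0.619048
indiv,1.213922,0.634921
indiv,1.217274,0.650794
indiv,1.217735,0.666667
indiv,1.219154,0.682540
indiv,1.222021,0.698413
indiv,1.222338,0.714286
indiv,1.224649,0.730159
indiv,1.227504,0.746032
indiv,1.230254,0.761905
indiv,1.233955,0.777778
indiv,1.238570,0.793651
indiv,1.239296,0.809524
indiv,1.242870,0.825397
indiv,1.243465,0.841270
indiv,1.245931,0.857143
indiv,1.247373,0.873016
indiv,1.249240,0.888889
indiv,1.253875,0.904762
indiv,1.254565,0.920635
indiv,1.260118,0.936508
indiv,1.260823,0.952381
indiv,1.285224,0.968254
indiv,1.295074,0.984127
indiv,1.302356,1.000000
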