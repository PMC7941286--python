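energy_keV,mu_total,mu_photoelectric,mu_incoherent,mu_coherent
5,40.27,39.6641,0.133286,0.472613
5.37524,32.4696,31.892,0.137379,0.440198
5.77865,26.1801,25.63,0.141304,0.408846
6.21233,21.1023,20.5786,0.145042,0.378675
6.67855,17.0036,16.5053,0.14858,0.349789
7.17977,13.701,13.2268,0.151906,0.322269
7.7186,11.0399,10.5887,0.15501,0.296179
8.29787,8.90204,8.47259,0.157886,0.271557
8.92062,7.18327,6.77432,0.16053,0.248422
9.5901,5.79635,5.40664,0.162942,0.226771
10.3098,4.69398,4.32227,0.165123,0.206586
11.0836,3.81997,3.46506,0.167076,0.187832
11.9154,3.10869,2.76942,0.168806,0.170463
12.8096,2.52985,2.20511,0.170318,0.154423
13.7709,2.0588,1.74753,0.17162,0.139649
14.8044,1.67545,1.37666,0.172718,0.126076
15.9155,1.38876,1.10151,0.173619,0.113633
17.1099,1.15583,0.879244,0.174331,0.102252
18.394,0.961959,0.695238,0.17486,0.0918623
19.7744,0.80061,0.543001,0.175213,0.0823966
21.2585,0.690918,0.441733,0.175397,0.0737891
22.8539,0.600286,0.358892,0.175418,0.0659768
24.5691,0.521543,0.287362,0.175281,0.0588996
26.4129,0.453128,0.225636,0.174992,0.0525006
28.3952,0.393689,0.172407,0.174556,0.0467258
30.5262,0.346325,0.130823,0.173977,0.0415243
32.8172,0.316876,0.106766,0.173261,0.0368483
35.28,0.28993,0.0848673,0.17241,0.0326528
37.9278,0.265276,0.0649514,0.171429,0.0288956
40.7742,0.244731,0.0521317,0.167062,0.0255372
43.8342,0.231011,0.0409518,0.167518,0.0225407
47.1239,0.21806,0.0321416,0.166046,0.0198719
50.6605,0.206452,0.025205,0.163748,0.0174989
54.4625,0.198123,0.0197484,0.162982,0.0153924
58.5499,0.190129,0.0154597,0.161144,0.0135254
62.9439,0.183773,0.0120918,0.159808,0.011873
67.6678,0.178282,0.00944953,0.15842,0.0104126
72.7462,0.172955,0.00737823,0.156454,0.00912366
78.2057,0.167788,0.00575597,0.154044,0.00798741
84.0749,0.163426,0.00448652,0.151953,0.00698698
90.3846,0.159469,0.00349402,0.149868,0.00610712
97.1678,0.155607,0.00271872,0.147554,0.00533415
104.46,0.151994,0.00211363,0.145224,0.00465577
112.3,0.148563,0.00164179,0.142861,0.00406099
120.728,0.145211,0.00127418,0.140397,0.00353999
129.788,0.141934,0.00098803,0.137862,0.00308403
139.529,0.138731,0.000765478,0.13528,0.00268532
150,0.1356,0.000592542,0.132671,0.00233694
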