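energy_keV,mu_total,mu_photoelectric,mu_incoherent,mu_coherent
5,587,580.065,0.0668371,6.86825
5.37524,483.459,476.812,0.0705776,6.57635
5.77865,398.181,391.823,0.0743149,6.2832
6,360,353.793,0.0762513,6.13065
6.21233,328.785,322.718,0.0780382,5.98948
6.67855,272.235,266.458,0.0817364,5.69588
7.17977,225.412,219.923,0.0853978,5.40316
7.7186,186.642,181.44,0.0890098,5.11214
8,170,164.94,0.0907745,4.96904
8.29787,155.046,150.13,0.0925584,4.82372
8.92062,129.213,124.578,0.0960287,4.53889
9.5901,107.684,103.326,0.0994049,4.25872
10,96.91,92.7095,0.101308,4.09924
10.207,222,217.876,0.102225,4.02194
10.3098,215.582,211.495,0.10267,3.98432
11.0836,174.433,170.61,0.105809,3.71683
11.54,155,151.321,0.107498,3.57107
11.544,215,211.323,0.107512,3.56983
11.9154,197.835,194.269,0.108804,3.45735
12.1,190,186.487,0.109421,3.40335
12.104,219,215.488,0.109434,3.40219
12.8096,194.222,190.903,0.111642,3.20692
13.7709,166.608,163.527,0.114307,2.96646
14.8044,142.92,140.067,0.11679,2.73673
15,139,136.187,0.11722,2.69628
15.9155,119.134,116.497,0.119081,2.51837
17.1099,98.6779,96.2449,0.121172,2.31178
18.394,81.7341,79.4938,0.123061,2.11722
19.7744,67.6998,65.6402,0.124743,1.93477
20,65.73,63.6977,0.124988,1.90727
21.2585,56.0218,54.1312,0.12622,1.76435
22.8539,46.3501,44.6168,0.127492,1.60573
24.5691,38.3481,36.7609,0.128563,1.4586
26.4129,31.7275,30.2756,0.129436,1.32253
28.3952,26.25,24.9229,0.130116,1.19704
30,22.73,21.491,0.130508,1.10846
30.5262,21.7144,20.5022,0.13061,1.08161
32.8172,17.9527,16.8461,0.130922,0.97568
35.28,14.8427,13.833,0.131059,0.87868
37.9278,12.2715,11.3504,0.131028,0.790043
40,10.67,9.80921,0.1309,0.729893
40.7742,10.1477,9.30767,0.130833,0.709209
43.8342,8.39626,7.63015,0.130482,0.635632
47.1239,6.94711,6.24834,0.129981,0.568787
50,5.949,5.30081,0.129463,0.518726
50.6605,5.75053,5.11302,0.129336,0.508174
54.4625,4.76927,4.18741,0.128552,0.453314
58.5499,3.95546,3.42406,0.127637,0.403757
60,3.713,3.19758,0.127298,0.388125
62.9439,3.29004,2.80437,0.126595,0.359075
67.6678,2.74063,2.29633,0.125433,0.318867
69.52,2.56,2.1301,0.124971,0.304931
69.53,11.23,10.8002,0.124968,0.304859
72.7462,9.98926,9.58234,0.124158,0.282754
78.2057,8.28246,7.9093,0.122775,0.250384
80,7.81,7.44673,0.12232,0.240953
84.0749,6.88653,6.54381,0.12129,0.221421
90.3846,5.73318,5.41792,0.119709,0.195557
97.1678,4.773,4.48246,0.11804,0.172501
100,4.438,4.15658,0.117354,0.164066
104.46,3.97143,3.70316,0.116288,0.151984
112.3,3.30327,3.05505,0.11446,0.133757
120.728,2.74752,2.51737,0.112563,0.11759
129.788,2.28527,2.0714,0.110602,0.103272
139.529,1.90079,1.7016,0.108585,0.090609
150,1.581,1.39506,0.106519,0.0794257
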