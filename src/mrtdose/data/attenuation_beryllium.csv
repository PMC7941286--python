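energy_keV,mu_total,mu_photoelectric,mu_incoherent,mu_coherent
5,4.369,4.05545,0.12879,0.184764
5.37524,3.51565,3.2129,0.132034,0.170708
5.77865,2.82897,2.53657,0.135095,0.15731
6.21233,2.29126,2.00869,0.137964,0.1446
6.67855,1.86883,1.59559,0.140635,0.132601
7.17977,1.52428,1.25985,0.143105,0.121322
7.7186,1.24326,0.987119,0.145372,0.110764
8.29787,1.02666,0.778303,0.147437,0.100918
8.92062,0.858125,0.617056,0.149302,0.0917675
9.5901,0.717259,0.482994,0.150973,0.0832911
10.3098,0.611353,0.383437,0.152454,0.075462
11.0836,0.535249,0.313247,0.153752,0.0682501
11.9154,0.468618,0.252124,0.154871,0.0616232
12.8096,0.410282,0.198915,0.155819,0.0555476
13.7709,0.359208,0.152615,0.156603,0.0499894
14.8044,0.314492,0.112348,0.157229,0.0449149
15.9155,0.287996,0.0900022,0.157703,0.0402911
17.1099,0.266371,0.0722546,0.158031,0.0360859
18.394,0.24637,0.0558832,0.158218,0.0322687
19.7744,0.227871,0.0436004,0.15546,0.0288102
21.2585,0.217505,0.0339228,0.1579,0.0256826
22.8539,0.208831,0.0263549,0.159616,0.0228596
24.5691,0.200502,0.0204456,0.15974,0.0203166
26.4129,0.192505,0.0158382,0.158637,0.0180301
28.3952,0.184828,0.0122512,0.156598,0.0159783
30.5262,0.178243,0.00946287,0.154639,0.0141406
32.8172,0.174312,0.00729851,0.154516,0.0124977
35.28,0.170469,0.00562101,0.153816,0.0110318
37.9278,0.16671,0.00432278,0.152661,0.00972607
40.7742,0.163243,0.00331955,0.151358,0.00856498
43.8342,0.160416,0.00254545,0.150336,0.0075342
47.1239,0.157638,0.00194903,0.149069,0.00662054
50.6605,0.154953,0.00149019,0.147651,0.00581188
54.4625,0.152509,0.00113771,0.146274,0.00509716
58.5499,0.150104,0.000867341,0.144771,0.0044663
62.9439,0.147727,0.000660263,0.143157,0.00391015
67.6678,0.145383,0.000501895,0.14146,0.00342047
72.7462,0.143075,0.000380958,0.139704,0.00298979
78.2057,0.140804,0.000288742,0.137904,0.00261142
84.0749,0.138441,0.00021853,0.135943,0.00227934
90.3846,0.136059,0.000165151,0.133906,0.00198818
97.1678,0.133718,0.000124629,0.13186,0.00173313
104.46,0.131241,9.39128e-05,0.129637,0.00150991
112.3,0.128696,7.06642e-05,0.127311,0.00131471
120.728,0.1262,5.30936e-05,0.125003,0.00114416
129.788,0.123753,3.9834e-05,0.122718,0.000995248
139.529,0.121353,2.98424e-05,0.120458,0.000865326
150,0.119,2.23245e-05,0.118226,0.000752047
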