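energy_keV,mu_total,mu_photoelectric,mu_incoherent,mu_coherent
5,193.4,192.329,0.116988,0.953779
5.37524,157.507,156.491,0.121234,0.894877
5.77865,128.275,127.312,0.125363,0.837193
6.21233,104.306,103.396,0.129356,0.780963
6.67855,84.6745,83.8149,0.133193,0.726421
7.17977,68.7377,67.927,0.136858,0.673783
7.7186,55.8004,55.0368,0.140334,0.623242
8.29787,45.2333,44.5147,0.143607,0.574962
8.92062,36.6161,35.9403,0.146667,0.529071
9.5901,29.6404,29.0053,0.149506,0.485658
10.3098,23.9776,23.3807,0.152118,0.444775
11.0836,19.3788,18.8179,0.154502,0.406437
11.9154,15.662,15.1348,0.156656,0.370628
12.8096,12.6581,12.1622,0.158583,0.337302
13.7709,10.2303,9.76367,0.160286,0.306388
14.8044,8.26821,7.82864,0.16177,0.277801
15.9155,6.69408,6.2796,0.163041,0.251437
17.1099,5.42174,5.03045,0.164105,0.227187
18.394,4.39123,4.02133,0.164969,0.204933
19.7744,3.55659,3.2064,0.16564,0.184556
21.2585,2.90927,2.57722,0.166124,0.165936
22.8539,2.38416,2.06878,0.166428,0.148955
24.5691,1.95382,1.65377,0.166559,0.133499
26.4129,1.60117,1.31518,0.166523,0.119458
28.3952,1.31216,1.03911,0.166326,0.106726
30.5262,1.08224,0.821061,0.165973,0.0952032
32.8172,0.910893,0.660629,0.16547,0.0847939
35.28,0.766676,0.526446,0.164822,0.075409
37.9278,0.645293,0.414297,0.164032,0.0669638
40.7742,0.547664,0.325178,0.163107,0.0593792
43.8342,0.475661,0.261031,0.162049,0.0525804
47.1239,0.413124,0.205762,0.160865,0.0464977
50.6605,0.360718,0.160095,0.159557,0.0410657
54.4625,0.32259,0.128236,0.158131,0.0362237
58.5499,0.288493,0.0999881,0.15659,0.0319149
62.9439,0.263402,0.0803769,0.154938,0.0280871
67.6678,0.243054,0.0651803,0.153181,0.024692
72.7462,0.224277,0.0512689,0.151323,0.0216851
78.2057,0.206951,0.0394623,0.148462,0.019026
84.0749,0.194342,0.0310456,0.146619,0.0166776
90.3846,0.18397,0.024404,0.14496,0.0146062
97.1678,0.174151,0.0191674,0.142202,0.0127814
104.46,0.16655,0.0150421,0.140332,0.0111757
112.3,0.160356,0.0117949,0.138797,0.00976443
120.728,0.154393,0.00924102,0.136626,0.00852526
129.788,0.148651,0.00723417,0.133978,0.00743831
139.529,0.143123,0.00565847,0.130978,0.00648581
150,0.1378,0.00442233,0.127726,0.00565187
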