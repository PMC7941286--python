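q_inv_angstrom,F2_molecule,S_molecule
0.001,66,4.31218e-06
0.00107979,66,5.02778e-06
0.00116595,66,5.86213e-06
0.00125898,66,6.83495e-06
0.00135944,65.9999,7.9692e-06
0.00146791,65.9999,9.29168e-06
0.00158504,65.9999,1.08336e-05
0.00171151,65.9999,1.26315e-05
0.00184807,65.9999,1.47276e-05
0.00199553,65.9999,1.71717e-05
0.00215476,65.9999,2.00213e-05
0.00232669,65.9998,2.33438e-05
0.00251234,65.9998,2.72177e-05
0.0027128,65.9998,3.17344e-05
0.00292926,65.9997,3.70006e-05
0.00316299,65.9997,4.31408e-05
0.00341536,65.9996,5.03e-05
0.00368788,65.9996,5.86471e-05
0.00398214,65.9995,6.83795e-05
0.00429988,65.9994,7.97269e-05
0.00464297,65.9993,9.29573e-05
0.00501344,65.9992,0.000108383
0.00541347,65.9991,0.000126369
0.00584542,65.999,0.000147339
0.00631183,65.9988,0.00017179
0.00681546,65.9986,0.000200297
0.00735928,65.9983,0.000233535
0.00794648,65.9981,0.000272289
0.00858054,65.9977,0.000317473
0.00926519,65.9974,0.000370155
0.0100045,65.9969,0.000431578
0.0108027,65.9964,0.000503193
0.0116647,65.9958,0.00058669
0.0125955,65.9951,0.000684041
0.0136005,65.9943,0.000797545
0.0146857,65.9934,0.000929879
0.0158574,65.9923,0.00108417
0.0171227,65.991,0.00126405
0.018489,65.9895,0.00147378
0.0199642,65.9878,0.00171829
0.0215572,65.9858,0.00200336
0.0232773,65.9834,0.0023357
0.0251346,65.9807,0.00272316
0.0271401,65.9775,0.00317487
0.0293057,65.9738,0.00370146
0.031644,65.9694,0.00431533
0.0341689,65.9643,0.00503095
0.0368953,65.9584,0.00586514
0.0398392,65.9515,0.00683751
0.0430181,65.9435,0.00797091
0.0464505,65.9341,0.00929194
0.0501569,65.9232,0.0108316
0.0541589,65.9105,0.0126258
0.0584804,65.8957,0.0147167
0.0631466,65.8784,0.017153
0.0681851,65.8583,0.0199915
0.0736257,65.8348,0.0232981
0.0795004,65.8076,0.0271496
0.0858438,65.7758,0.0316349
0.0926934,65.7388,0.0368573
0.10009,65.6957,0.0429366
0.108076,65.6456,0.0500115
0.116699,65.5873,0.0582426
0.126011,65.5196,0.0678153
0.136065,65.4408,0.0789437
0.146922,65.3493,0.0918744
0.158645,65.2431,0.106891
0.171304,65.1199,0.124318
0.184973,64.9771,0.144528
0.199732,64.8117,0.167945
0.215669,64.6205,0.19505
0.232877,64.3995,0.226387
0.251459,64.1446,0.26257
0.271523,63.8511,0.304282
0.293188,63.5137,0.352285
0.316582,63.1268,0.407413
0.341842,62.6843,0.470579
0.369118,62.1795,0.542765
0.398571,61.6058,0.625011
0.430373,60.956,0.718405
0.464713,60.2232,0.824054
0.501793,59.4006,0.943062
0.541832,58.4823,1.07649
0.585065,57.4628,1.22531
0.631748,56.3384,1.39035
0.682156,55.1067,1.57227
0.736587,53.7677,1.77147
0.79536,52.3235,1.98807
0.858822,50.7787,2.22187
0.927349,49.1406,2.47232
1.00134,47.4189,2.73855
1.08124,45.625,3.01932
1.16752,43.772,3.31313
1.26067,41.8737,3.61823
1.36126,39.9438,3.93268
1.46988,37.9953,4.25437
1.58716,36.04,4.58113
1.71381,34.0879,4.9107
1.85055,32.1471,5.24079
1.99821,30.2241,5.56909
2.15765,28.3237,5.89332
2.32981,26.4498,6.21125
2.51571,24.6055,6.52076
2.71644,22.7944,6.8199
2.93319,21.0202,7.10698
3.16723,19.288,7.38058
3.41995,17.6038,7.6396
3.69283,15.975,7.88325
3.98749,14.4098,8.111
4.30566,12.9172,8.32258
4.64921,11.5061,8.51787
5.02018,10.1846,8.69695
5.42074,8.95973,8.86
5.85327,7.83621,9.00736
6.32031,6.81657,9.13951
6.82462,5.90077,9.25709
7.36916,5.08633,9.36092
7.95716,4.36857,9.45192
8.59207,3.74111,9.53115
9.27764,3.19635,9.59974
10.0179,2.72605,9.65882
10.8173,2.32172,9.70954
11.6804,1.97513,9.75297
12.6124,1.67851,9.79011
13.6187,1.42477,9.82186
14.7054,1.20765,9.84902
15.8787,1.02169,9.87227
17.1457,0.862249,9.89221
18.5138,0.72542,9.90932
19.9911,0.607963,9.924
21.5862,0.507199,9.9366
23.3086,0.42091,9.94739
25.1684,0.347245,9.95659
27.1766,0.284635,9.96442
29.345,0.231723,9.97103
31.6865,0.18731,9.97659
34.2148,0.150315,9.98121
36.9449,0.119756,9.98503
39.8927,0.0947318,9.98816
43.0758,0.0744212,9.9907
46.5129,0.058081,9.99274
50.2242,0.0450478,9.99437
54.2317,0.0347373,9.99566
58.5589,0.0266438,9.99667
63.2314,0.0203363,9.99746
68.2767,0.0154533,9.99807
73.7246,0.011696,9.99854
79.6072,0.00882064,9.9989
85.9591,0.00663103,9.99917
92.8179,0.00497094,9.99938
100.224,0.00371721,9.99954
108.221,0.00277362,9.99965
116.856,0.0020656,9.99974
126.18,0.00153576,9.99981
136.248,0.00114016,9.99986
147.12,0.0008454,9.99989
158.859,0.000626155,9.99992
171.534,0.000463328,9.99994
185.221,0.000342562,9.99996
200,0.000253094,9.99997
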