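energy_keV,mu_total,mu_photoelectric,mu_incoherent,mu_coherent
5,42.58,41.9522,0.151602,0.476198
5.37524,34.2699,33.6702,0.1562,0.443544
5.77865,27.5816,27.0091,0.160559,0.411967
6.21233,22.1924,21.6462,0.164669,0.381584
6.67855,17.8508,17.3298,0.168522,0.352493
7.17977,14.3585,13.8617,0.172111,0.324777
7.7186,11.5495,11.0756,0.175432,0.298498
8.29787,9.29844,8.84626,0.178485,0.273694
8.92062,7.49279,7.06113,0.18127,0.250386
9.5901,6.03778,5.62542,0.18379,0.228572
10.3098,4.88408,4.4898,0.186051,0.208232
11.0836,3.97176,3.59437,0.188057,0.189335
11.9154,3.22985,2.8682,0.189817,0.171832
12.8096,2.62653,2.27952,0.191339,0.15567
13.7709,2.1359,1.80249,0.192631,0.140784
14.8044,1.73693,1.41612,0.193703,0.127108
15.9155,1.44073,1.13159,0.194562,0.114572
17.1099,1.20029,0.90197,0.195217,0.103106
18.394,0.999984,0.711667,0.195677,0.0926394
19.7744,0.833103,0.55405,0.19595,0.0831036
21.2585,0.721225,0.450752,0.196042,0.0744323
22.8539,0.628841,0.36632,0.19596,0.0665617
24.5691,0.548291,0.293149,0.195711,0.0594311
26.4129,0.478059,0.229776,0.1953,0.0529831
28.3952,0.416823,0.174926,0.194733,0.0471632
30.5262,0.36804,0.132104,0.194015,0.0419202
32.8172,0.338176,0.10782,0.19315,0.0372059
35.28,0.310735,0.0856177,0.192142,0.0329752
37.9278,0.285521,0.0653398,0.190995,0.0291856
40.7742,0.264465,0.052402,0.186265,0.0257976
43.8342,0.250474,0.0410938,0.186606,0.022774
47.1239,0.237224,0.0321982,0.184945,0.0200805
50.6605,0.225319,0.0252064,0.182428,0.0176851
54.4625,0.216799,0.0197159,0.181525,0.0155583
58.5499,0.208601,0.015408,0.17952,0.0136729
62.9439,0.202026,0.012031,0.177991,0.012004
67.6678,0.19631,0.00938607,0.176395,0.0105288
72.7462,0.190757,0.00731628,0.174214,0.00922653
78.2057,0.18536,0.005698,0.171584,0.00807837
84.0749,0.180723,0.00443385,0.169221,0.0070673
90.3846,0.176472,0.00344718,0.166846,0.00617796
97.1678,0.172321,0.00267776,0.164246,0.00539655
104.46,0.168402,0.00207829,0.161613,0.00471068
112.3,0.164659,0.00161163,0.158938,0.00410925
120.728,0.160999,0.00124868,0.156168,0.00358237
129.788,0.15742,0.000966633,0.153332,0.00312119
139.529,0.153921,0.000747648,0.150456,0.00271788
150,0.1505,0.000577775,0.147557,0.00236545
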