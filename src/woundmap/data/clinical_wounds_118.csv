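id,RA,AC_2d,AC_ours,AE_2d,AE_ours
1,2.02,2.1456,1.9641,6.22,2.77
2,0.27,0.1544,0.2581,42.82,4.41
3,1.90,1.9257,1.8883,1.35,0.61
4,5.03,2.9112,5.2029,42.12,3.44
5,9.91,9.4237,9.9797,4.91,0.70
6,0.20,0.1820,0.2078,9.00,3.89
7,1.33,1.2343,1.3485,7.19,1.39
8,12.50,7.5514,13.2206,39.59,5.76
9,1.09,1.0202,1.1145,6.41,2.25
10,0.11,0.1015,0.1065,7.74,3.19
11,0.99,0.6230,1.0458,37.07,5.64
12,6.74,6.9441,6.6396,3.03,1.49
13,0.23,0.2195,0.2347,4.56,2.04
14,0.23,0.2355,0.2255,2.40,1.95
15,6.20,5.4769,6.3677,11.66,2.70
16,0.59,0.5509,0.6075,6.63,2.97
17,0.88,0.8151,0.9091,7.38,3.30
18,3.99,4.0891,3.9113,2.48,1.97
19,0.72,0.8002,0.7487,11.14,3.99
20,2.98,3.0852,2.9614,3.53,0.62
21,1.80,2.7304,1.7449,51.69,3.06
22,2.04,1.9410,2.0404,4.85,0.02
23,2.47,2.6954,2.4928,9.13,0.92
24,5.96,5.0697,6.0596,14.94,1.67
25,3.06,2.1524,3.1713,29.66,3.64
26,0.97,0.7183,1.0164,25.94,4.78
27,3.49,3.4324,3.4955,1.65,0.16
28,12.14,12.6043,12.1365,3.82,0.03
29,4.65,3.9788,4.7489,14.44,2.13
30,0.84,0.6692,0.8794,20.34,4.69
31,0.89,0.8189,0.9227,7.99,3.67
32,8.17,6.0788,8.5622,25.60,4.80
33,1.40,1.4173,1.3779,1.24,1.58
34,1.37,1.2933,1.3213,5.60,3.56
35,0.74,0.6854,0.7051,7.38,4.71
36,1.35,1.1543,1.4025,14.50,3.89
37,0.59,0.4972,0.6038,15.73,2.34
38,5.10,3.6088,5.3373,29.24,4.65
39,1.44,1.3620,1.4128,5.42,1.89
40,0.11,0.1249,0.1131,13.57,2.85
41,0.89,0.8149,0.9306,8.44,4.57
42,2.14,2.0095,2.1400,6.10,0.00
43,0.27,0.2066,0.2830,23.49,4.83
44,4.41,4.1795,4.5546,5.23,3.28
45,2.25,1.7818,2.2985,20.81,2.15
46,1.59,1.1074,1.6206,30.35,1.92
47,1.04,1.6420,1.0235,57.88,1.58
48,2.02,2.3111,1.9642,14.41,2.76
49,2.13,2.4079,2.0971,13.05,1.55
50,2.64,2.4554,2.6605,6.99,0.78
51,0.15,0.2385,0.1383,59.03,7.83
52,0.23,0.1250,0.2439,45.66,6.03
53,0.57,0.5687,0.5419,0.24,4.93
54,1.11,0.8933,1.2041,19.53,8.47
55,1.59,1.2239,1.6628,23.02,4.58
56,1.67,2.3435,1.5873,40.33,4.95
57,2.34,2.9862,2.2232,27.61,4.99
58,3.49,4.4483,3.3186,27.46,4.91
59,6.91,7.8040,6.5722,12.94,4.89
60,0.78,0.8173,0.7533,4.78,3.43
61,3.03,3.1793,2.9266,4.93,3.41
62,4.35,4.3271,4.3493,0.53,0.02
63,3.67,5.4157,3.5271,47.57,3.89
64,1.25,1.1972,1.2581,4.23,0.65
65,3.64,3.6731,3.6411,0.91,0.03
66,1.85,2.4991,1.8362,35.08,0.75
67,0.39,0.4435,0.3890,13.71,0.26
68,0.15,0.1520,0.1450,1.35,3.32
69,0.61,0.6762,0.5812,10.84,4.73
70,1.12,1.1793,1.1410,5.29,1.98
71,0.18,0.1984,0.1795,10.22,0.28
72,0.89,0.7812,0.9094,12.22,2.18
73,0.28,0.2810,0.2825,0.34,0.91
74,0.34,0.2691,0.3529,20.84,3.79
75,0.96,0.4828,0.9796,49.70,2.04
76,2.72,1.6988,2.8421,37.54,4.49
77,1.48,0.8552,1.5444,42.22,4.35
78,3.05,4.0327,2.9880,32.22,2.03
79,1.61,0.9655,1.5669,40.03,2.68
80,0.36,0.1964,0.3722,45.45,3.39
81,2.79,2.2028,2.8371,21.05,1.69
82,2.20,1.3042,2.3150,40.72,5.23
83,1.66,1.6802,1.6637,1.22,0.22
84,1.69,1.2231,1.7594,27.63,4.11
85,4.36,4.7699,4.1851,9.40,4.01
86,2.50,2.5650,2.5028,2.60,0.11
87,2.29,2.1020,2.3011,8.21,0.49
88,5.12,5.5105,5.0762,7.63,0.85
89,0.41,0.5473,0.3989,33.49,2.70
90,8.10,9.5860,7.9691,18.35,1.62
91,0.38,0.5559,0.3731,46.29,1.82
92,2.29,2.0965,2.2347,8.45,2.41
93,0.45,0.2244,0.4401,50.14,2.20
94,0.76,0.7058,0.7765,7.13,2.17
95,8.03,7.9612,8.1409,0.86,1.38
96,3.25,3.7312,3.2752,14.71,0.78
97,11.26,11.8617,11.2349,5.23,0.22
98,3.78,3.8444,3.7817,1.70,0.04
99,0.80,1.0795,0.7856,34.93,1.80
100,0.47,0.5556,0.4623,18.21,1.65
101,1.00,1.0367,1.0077,3.67,0.77
102,0.46,0.5045,0.4387,9.66,4.62
103,0.50,0.3250,0.5174,35.00,3.49
104,6.98,5.5115,7.0106,21.04,0.44
105,2.28,1.4454,2.3099,36.60,1.31
106,0.31,0.2947,0.3106,4.92,0.20
107,0.35,0.3352,0.3586,4.23,2.46
108,4.73,4.9577,4.5500,4.81,3.81
109,0.45,0.4035,0.4575,10.33,1.66
110,0.22,0.2280,0.2019,3.66,8.23
111,0.50,0.4164,0.5394,16.72,7.87
112,0.64,0.9773,0.5563,52.71,13.08
113,1.36,0.9864,1.4244,27.47,4.74
114,1.62,2.4508,1.5403,51.28,4.92
115,2.30,1.3004,2.4115,43.46,4.85
116,3.13,4.1409,2.9426,32.30,5.99
117,4.18,3.3670,4.3813,19.45,4.82
118,8.53,7.4215,8.9107,12.99,4.46
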