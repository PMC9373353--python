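# Synthetic all-cause life table (age, annual death probability).
# Gompertz-like log-linear interpolation through plausible Ontario-level
# both-sex anchor values, scaled so e(60) matches the published ~25.4 y;
# a constructed stand-in, NOT an official statistical table.
age,qx
40,0.001000
41,0.001084
42,0.001176
43,0.001275
44,0.001383
45,0.001500
46,0.001634
47,0.001780
48,0.001939
49,0.002112
50,0.002300
51,0.002529
52,0.002782
53,0.003059
54,0.003364
55,0.003700
56,0.004116
57,0.004578
58,0.005092
59,0.005664
60,0.006300
61,0.006825
62,0.007394
63,0.008010
64,0.008677
65,0.009400
66,0.010223
67,0.011118
68,0.012091
69,0.013149
70,0.014300
71,0.015671
72,0.017173
73,0.018819
74,0.020623
75,0.022600
76,0.024969
77,0.027586
78,0.030477
79,0.033671
80,0.037200
81,0.041529
82,0.046361
83,0.051755
84,0.057777
85,0.064500
86,0.072408
87,0.081286
88,0.091252
89,0.102440
90,0.115000
91,0.127810
92,0.142047
93,0.157870
94,0.175456
95,0.195000
96,0.212546
97,0.231670
98,0.252515
99,0.275235
100,0.300000
101,0.317767
102,0.336587
103,0.356520
104,0.377635
105,0.400000
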