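# Synthetic all-cause female life table (Gompertz-Makeham shape),
# a stand-in for a national statistics life table: q(age) = min(1, 4e-4 + 8e-6*exp(0.11*age)).
age,qx
0,0.000408
1,0.000409
2,0.000410
3,0.000411
4,0.000412
5,0.000414
6,0.000415
7,0.000417
8,0.000419
9,0.000422
10,0.000424
11,0.000427
12,0.000430
13,0.000433
14,0.000437
15,0.000442
16,0.000446
17,0.000452
18,0.000458
19,0.000465
20,0.000472
21,0.000481
22,0.000490
23,0.000500
24,0.000512
25,0.000525
26,0.000540
27,0.000556
28,0.000574
29,0.000594
30,0.000617
31,0.000642
32,0.000670
33,0.000702
34,0.000737
35,0.000776
36,0.000820
37,0.000868
38,0.000923
39,0.000984
40,0.001052
41,0.001127
42,0.001212
43,0.001306
44,0.001412
45,0.001529
46,0.001661
47,0.001807
48,0.001971
49,0.002154
50,0.002358
51,0.002585
52,0.002839
53,0.003123
54,0.003439
55,0.003793
56,0.004187
57,0.004628
58,0.005119
59,0.005668
60,0.006281
61,0.006965
62,0.007728
63,0.008580
64,0.009531
65,0.010593
66,0.011778
67,0.013101
68,0.014578
69,0.016227
70,0.018067
71,0.020121
72,0.022414
73,0.024974
74,0.027831
75,0.031021
76,0.034582
77,0.038556
78,0.042993
79,0.047945
80,0.053474
81,0.059645
82,0.066534
83,0.074224
84,0.082808
85,0.092391
86,0.103087
87,0.115027
88,0.128356
89,0.143234
90,0.159843
91,0.178383
92,0.199078
93,0.222180
94,0.247968
95,0.276755
96,0.308889
97,0.344760
98,0.384801
99,0.429498
100,0.479393
101,0.535090
102,0.597262
103,0.666664
104,0.744136
105,0.830616
106,0.927152
107,1.000000
108,1.000000
109,1.000000
110,1.000000
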