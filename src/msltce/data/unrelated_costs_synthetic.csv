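age,sex,annual_cost
0,male,501.44
0,female,501.92
1,male,501.61
1,female,502.34
2,male,501.80
2,female,502.88
3,male,502.01
3,female,503.59
4,male,502.25
4,female,504.53
5,male,502.51
5,female,505.77
6,male,502.81
6,female,507.39
7,male,503.14
7,female,509.48
8,male,503.51
8,female,512.18
9,male,503.92
9,female,515.61
10,male,504.38
10,female,519.92
11,male,504.89
11,female,525.27
12,male,505.47
12,female,531.82
13,male,506.11
13,female,539.71
14,male,506.83
14,female,549.08
15,male,507.63
15,female,560.03
16,male,508.52
16,female,572.61
17,male,509.52
17,female,586.83
18,male,510.64
18,female,602.61
19,male,511.89
19,female,619.78
20,male,513.28
20,female,638.12
21,male,514.84
21,female,657.28
22,male,516.57
22,female,676.87
23,male,518.52
23,female,696.41
24,male,520.68
24,female,715.38
25,male,523.11
25,female,733.26
26,male,525.81
26,female,749.52
27,male,528.83
27,female,763.68
28,male,532.20
28,female,775.35
29,male,535.96
29,female,784.23
30,male,540.16
30,female,790.16
31,male,544.84
31,female,793.11
32,male,550.07
32,female,793.22
33,male,555.90
33,female,790.75
34,male,562.40
34,female,786.11
35,male,569.64
35,female,779.80
36,male,577.72
36,female,772.42
37,male,586.72
37,female,764.62
38,male,596.75
38,female,757.05
39,male,607.92
39,female,750.36
40,male,620.35
40,female,745.18
41,male,634.17
41,female,742.07
42,male,649.55
42,female,741.52
43,male,666.63
43,female,743.95
44,male,685.61
44,female,749.70
45,male,706.67
45,female,759.07
46,male,730.03
46,female,772.28
47,male,755.91
47,female,789.51
48,male,784.56
48,female,810.91
49,male,816.23
49,female,836.61
50,male,851.22
50,female,866.77
51,male,889.82
51,female,901.51
52,male,932.32
52,female,941.00
53,male,979.07
53,female,985.42
54,male,1030.40
54,female,1034.98
55,male,1086.64
55,female,1089.89
56,male,1148.13
56,female,1150.42
57,male,1215.22
57,female,1216.80
58,male,1288.23
58,female,1289.31
59,male,1367.47
59,female,1368.19
60,male,1453.21
60,female,1453.70
61,male,1545.71
61,female,1546.03
62,male,1645.15
62,female,1645.35
63,male,1751.65
63,female,1751.78
64,male,1865.27
64,female,1865.36
65,male,1985.98
65,female,1986.03
66,male,2113.65
66,female,2113.68
67,male,2248.04
67,female,2248.05
68,male,2388.79
68,female,2388.81
69,male,2535.46
69,female,2535.47
70,male,2687.46
70,female,2687.46
71,male,2844.09
71,female,2844.10
72,male,3004.58
72,female,3004.58
73,male,3168.03
73,female,3168.03
74,male,3333.50
74,female,3333.50
75,male,3500.00
75,female,3500.00
76,male,3666.50
76,female,3666.50
77,male,3831.97
77,female,3831.97
78,male,3995.42
78,female,3995.42
79,male,4155.91
79,female,4155.91
80,male,4312.54
80,female,4312.54
81,male,4464.54
81,female,4464.54
82,male,4611.21
82,female,4611.21
83,male,4751.96
83,female,4751.96
84,male,4886.35
84,female,4886.35
85,male,5014.02
85,female,5014.02
86,male,5134.73
86,female,5134.73
87,male,5248.35
87,female,5248.35
88,male,5354.85
88,female,5354.85
89,male,5454.29
89,female,5454.29
90,male,5546.79
90,female,5546.79
91,male,5632.53
91,female,5632.53
92,male,5711.77
92,female,5711.77
93,male,5784.78
93,female,5784.78
94,male,5851.87
94,female,5851.87
95,male,5913.36
95,female,5913.36
96,male,5969.60
96,female,5969.60
97,male,6020.93
97,female,6020.93
98,male,6067.68
98,female,6067.68
99,male,6110.18
99,female,6110.18
100,male,6148.78
100,female,6148.78
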