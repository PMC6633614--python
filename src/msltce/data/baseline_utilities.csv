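age,male,female
0,1.000,1.000
1,1.000,1.000
2,1.000,1.000
3,1.000,1.000
4,1.000,1.000
5,1.000,1.000
6,1.000,1.000
7,1.000,1.000
8,1.000,1.000
9,1.000,1.000
10,0.916,0.916
11,0.916,0.916
12,0.916,0.916
13,0.916,0.916
14,0.915,0.915
15,0.915,0.915
16,0.915,0.915
17,0.914,0.914
18,0.914,0.914
19,0.914,0.914
20,0.907,0.906
21,0.907,0.906
22,0.907,0.906
23,0.906,0.905
24,0.906,0.905
25,0.906,0.905
26,0.906,0.905
27,0.905,0.904
28,0.905,0.904
29,0.905,0.904
30,0.881,0.880
31,0.881,0.880
32,0.881,0.880
33,0.880,0.879
34,0.880,0.879
35,0.880,0.879
36,0.880,0.879
37,0.879,0.878
38,0.879,0.878
39,0.879,0.878
40,0.839,0.838
41,0.839,0.838
42,0.839,0.838
43,0.838,0.837
44,0.838,0.837
45,0.838,0.837
46,0.838,0.837
47,0.837,0.836
48,0.837,0.836
49,0.837,0.836
50,0.800,0.799
51,0.800,0.799
52,0.800,0.799
53,0.799,0.798
54,0.799,0.798
55,0.799,0.798
56,0.799,0.798
57,0.798,0.797
58,0.798,0.797
59,0.798,0.797
60,0.776,0.775
61,0.776,0.775
62,0.776,0.775
63,0.775,0.774
64,0.775,0.774
65,0.775,0.774
66,0.774,0.773
67,0.774,0.773
68,0.774,0.773
69,0.774,0.773
70,0.725,0.724
71,0.725,0.724
72,0.725,0.724
73,0.724,0.723
74,0.724,0.723
75,0.724,0.723
76,0.724,0.723
77,0.723,0.722
78,0.723,0.722
79,0.723,0.722
80,0.659,0.658
81,0.659,0.658
82,0.658,0.657
83,0.658,0.657
84,0.658,0.657
85,0.658,0.657
86,0.657,0.656
87,0.657,0.656
88,0.657,0.656
89,0.656,0.655
90,0.656,0.655
91,0.656,0.655
92,0.656,0.655
93,0.655,0.654
94,0.655,0.654
95,0.655,0.654
96,0.655,0.654
97,0.654,0.653
98,0.654,0.653
99,0.654,0.653
100,0.653,0.652
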