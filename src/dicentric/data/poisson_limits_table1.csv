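X,X_L,X_U
0,0,3.285
1,0.051,5.323
2,0.355,6.686
3,0.818,8.102
4,1.366,9.598
5,1.97,011.177
6,2.613,12.817
7,3.285,13.765
8,3.285,14.921
9,4.46,016.768
10,5.323,17.633
11,5.323,19.050
12,6.686,20.335
13,6.686,21.364
14,8.102,22.945
15,8.102,23.762
16,9.598,25.400
17,9.598,26.306
18,11.177,27.735
19,11.177,28.966
20,12.817,30.017
21,12.817,31.675
22,13.765,32.277
23,14.921,34.048
24,14.921,34.665
25,16.768,36.030
26,16.77,37.67
27,17.63,38.165
28,19.05,39.76
29,19.05,40.94
30,20.335,41.75
31,21.36,43.45
32,21.36,44.26
33,22.945,45.28
34,23.76,47.025
35,23.76,47.69
36,25.4,48.74
37,26.31,50.42
38,26.31,51.29
39,27.735,52.15
40,28.97,53.72
41,28.97,54.99
42,30.02,55.51
43,31.675,56.99
44,31.675,58.72
45,32.28,58.84
46,34.05,60.24
47,34.665,61.90
48,34.665,62.81
49,36.03,63.49
50,37.67,64.95
51,37.67,66.76
52,38.16,66.76
53,39.76,68.10
54,40.94,69.62
55,40.94,71.09
56,41.75,71.28
57,43.45,72.66
58,44.26,74.22
59,44.26,75.49
60,45.28,75.78
61,47.02,77.16
62,47.69,78.73
63,47.69,79.98
64,48.74,80.25
65,50.42,81.61
66,51.29,83.14
67,51.29,84.57
68,52.15,84.67
69,53.72,86.01
70,54.99,87.48
71,54.99,89.23
72,55.51,89.23
73,56.99,90.37
74,58.72,91.78
75,58.72,93.48
76,58.84,94.23
77,60.24,94.70
78,60.9,096.06
79,62.81,97.54
80,62.81,99.17
81,63.49,99.17
82,64.95,100.32
83,66.76,101.71
84,66.76,103.31
85,66.76,104.40
86,68.1,0104.58
87,69.62,105.90
88,71.09,107.32
89,71.09,109.11
90,71.28,109.61
91,72.66,110.11
92,74.22,111.44
93,75.49,112.87
94,75.49,114.84
95,75.78,114.84
96,77.16,115.60
97,78.73,116.93
98,79.98,118.35
99,79.98,120.36
100,80.25,120.36
101,81.61,121.06
102,83.14,122.37
103,84.57,123.77
104,84.57,125.46
105,84.67,126.26
106,86.01,126.48
107,87.48,127.78
108,89.23,129.14
109,89.23,130.68
110,89.23,132.03
111,90.37,132.03
112,91.78,133.14
113,93.48,134.48
114,94.23,135.92
115,94.23,137.79
116,94.7,0137.79
117,96.06,138.49
118,97.54,139.79
119,99.17,141.16
120,99.17,142.70
121,99.17,144.01
122,100.32,144.01
123,101.71,145.08
124,103.31,146.39
125,104.4,0147.80
126,104.4,0149.53
127,104.58,150.19
128,105.9,0150.36
129,107.32,151.63
130,109.11,152.96
131,109.61,154.39
132,109.61,156.32
133,110.11,156.32
134,111.44,156.87
135,112.87,158.15
136,114.84,159.48
137,114.84,160.92
138,114.84,162.79
139,115.6,0162.79
140,116.93,163.35
141,118.35,164.63
142,120.36,165.96
143,120.36,167.39
144,120.36,169.33
145,121.06,169.33
146,122.37,169.80
147,123.77,171.07
148,125.46,172.38
149,126.26,173.79
150,126.26,175.48
151,126.48,176.23
152,127.78,176.23
153,129.14,177.48
154,130.68,178.77
155,132.03,180.14
156,132.03,181.67
157,132.03,183.05
158,133.14,183.05
159,134.48,183.86
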