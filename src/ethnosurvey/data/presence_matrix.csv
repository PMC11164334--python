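code,A,B,C,D,E,F,G,H,I,J,K,L,M,N,novel
1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
2,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
3,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
4,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0
5,1,1,0,0,1,0,0,0,0,0,0,0,1,0,0
6,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0
7,0,0,0,1,0,0,0,0,0,0,0,1,0,0,0
8,1,0,0,0,0,0,0,0,0,0,0,0,0,1,0
9,1,1,0,0,1,0,1,0,1,0,0,0,0,0,0
10,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0
11,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0
12,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
13,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0
14,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
15,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
16,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
17,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
18,1,1,1,1,1,0,1,0,0,0,0,1,1,0,0
19,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
20,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
21,0,0,0,0,0,0,1,0,1,0,0,1,0,0,0
22,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
23,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
24,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
25,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
26,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
27,0,0,1,0,0,1,1,0,0,0,0,1,0,0,0
28,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
29,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
30,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
31,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
32,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
33,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
34,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
35,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
36,1,1,1,0,0,0,0,0,0,0,0,0,0,0,0
37,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
38,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
39,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
40,1,1,1,1,1,0,0,0,0,0,0,0,0,0,0
41,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
42,0,0,1,0,0,1,0,0,0,0,0,0,0,0,0
43,1,1,1,1,1,0,0,0,0,0,0,0,0,0,0
44,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
45,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
46,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
47,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
48,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
49,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
50,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
51,0,1,1,0,0,0,0,0,0,0,1,0,0,0,0
52,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0
53,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
54,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
55,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
56,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
57,1,1,0,0,0,0,1,1,0,0,0,0,0,0,0
58,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0
59,0,1,1,0,0,0,0,0,1,1,0,0,0,1,0
60,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
61,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0
62,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
63,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
64,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
65,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
66,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
67,1,1,1,0,1,1,0,0,1,0,0,0,0,0,0
68,1,1,0,0,1,0,0,0,0,0,0,0,0,0,0
69,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
70,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
71,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
72,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
73,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
74,0,0,1,0,1,1,0,0,0,0,0,1,0,1,0
75,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
76,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
77,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
78,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
79,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
80,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
81,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
82,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
83,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
84,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
85,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0
86,1,1,0,0,0,0,1,1,0,0,0,0,0,0,0
87,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
88,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
89,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
90,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
91,0,0,0,0,0,0,1,0,0,1,0,0,1,0,0
92,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
93,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
94,1,1,1,1,1,0,0,0,0,0,0,1,0,0,0
95,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
96,0,1,1,0,1,0,0,0,0,0,0,0,0,0,0
97,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
98,1,0,0,1,0,0,0,0,0,0,0,0,1,1,0
99,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
100,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
101,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
102,0,0,0,0,0,0,0,1,0,0,1,0,0,0,0
103,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0
104,1,0,1,1,1,0,0,0,0,0,0,0,0,0,0
105,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0
106,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
107,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
108,1,1,1,0,0,0,0,0,0,0,0,0,0,0,0
109,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
110,1,0,0,0,1,0,0,0,0,0,0,0,1,0,0
111,1,0,0,0,0,1,0,0,0,0,0,0,0,0,0
112,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
113,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
114,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
115,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0
116,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
117,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
118,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
119,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0
120,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
121,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
122,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0
123,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0
124,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
125,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
126,0,0,1,0,1,1,0,0,0,0,0,0,1,0,0
127,0,0,1,0,0,1,0,0,0,0,0,0,0,0,0
128,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
129,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0
130,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
131,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
132,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
133,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
134,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0
135,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
136,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
137,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
138,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
139,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
140,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0
141,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
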