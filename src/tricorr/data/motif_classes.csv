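config_id,temporal_order_code,spatial_order_code,class_label
1,000,000,0
2,000,001,III
3,000,010,III
4,000,011,III
5,000,012,IV
6,000,021,IV
7,000,100,III
8,000,101,III
9,000,102,IV
10,000,110,III
11,000,120,IV
12,000,201,IV
13,000,210,IV
14,001,000,I
15,001,001,V
16,001,010,VII
17,001,011,VII
18,001,012,XII
19,001,021,XII
20,001,100,VII
21,001,101,VII
22,001,102,XII
23,001,110,V
24,001,120,XII
25,001,201,XII
26,001,210,XII
27,010,000,I
28,010,001,VII
29,010,010,V
30,010,011,VII
31,010,012,XII
32,010,021,XII
33,010,100,VII
34,010,101,V
35,010,102,XII
36,010,110,VII
37,010,120,XII
38,010,201,XII
39,010,210,XII
40,011,000,I
41,011,001,VI
42,011,010,VI
43,011,011,V
44,011,012,XI
45,011,021,XI
46,011,100,V
47,011,101,VI
48,011,102,XI
49,011,110,VI
50,011,120,XI
51,011,201,XI
52,011,210,XI
53,012,000,II
54,012,001,X
55,012,010,IX
56,012,011,VIII
57,012,012,XIII
58,012,021,XIII
59,012,100,VIII
60,012,101,IX
61,012,102,XIII
62,012,110,X
63,012,120,XIII
64,012,201,XIII
65,012,210,XIII
66,021,000,II
67,021,001,IX
68,021,010,X
69,021,011,VIII
70,021,012,XIII
71,021,021,XIII
72,021,100,VIII
73,021,101,X
74,021,102,XIII
75,021,110,IX
76,021,120,XIII
77,021,201,XIII
78,021,210,XIII
79,100,000,I
80,100,001,VII
81,100,010,VII
82,100,011,V
83,100,012,XII
84,100,021,XII
85,100,100,V
86,100,101,VII
87,100,102,XII
88,100,110,VII
89,100,120,XII
90,100,201,XII
91,100,210,XII
92,101,000,I
93,101,001,VI
94,101,010,V
95,101,011,VI
96,101,012,XI
97,101,021,XI
98,101,100,VI
99,101,101,V
100,101,102,XI
101,101,110,VI
102,101,120,XI
103,101,201,XI
104,101,210,XI
105,102,000,II
106,102,001,X
107,102,010,VIII
108,102,011,IX
109,102,012,XIII
110,102,021,XIII
111,102,100,IX
112,102,101,VIII
113,102,102,XIII
114,102,110,X
115,102,120,XIII
116,102,201,XIII
117,102,210,XIII
118,110,000,I
119,110,001,V
120,110,010,VI
121,110,011,VI
122,110,012,XI
123,110,021,XI
124,110,100,VI
125,110,101,VI
126,110,102,XI
127,110,110,V
128,110,120,XI
129,110,201,XI
130,110,210,XI
131,120,000,II
132,120,001,VIII
133,120,010,X
134,120,011,IX
135,120,012,XIII
136,120,021,XIII
137,120,100,IX
138,120,101,X
139,120,102,XIII
140,120,110,VIII
141,120,120,XIII
142,120,201,XIII
143,120,210,XIII
144,201,000,II
145,201,001,IX
146,201,010,VIII
147,201,011,X
148,201,012,XIII
149,201,021,XIII
150,201,100,X
151,201,101,VIII
152,201,102,XIII
153,201,110,IX
154,201,120,XIII
155,201,201,XIII
156,201,210,XIII
157,210,000,II
158,210,001,VIII
159,210,010,IX
160,210,011,X
161,210,012,XIII
162,210,021,XIII
163,210,100,X
164,210,101,IX
165,210,102,XIII
166,210,110,VIII
167,210,120,XIII
168,210,201,XIII
169,210,210,XIII
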