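>W2 B 171
1 8 20 64 8
2 4 4 4 88
3 4 88 4 4
4 4 4 4 88
5 88 4 4 4
6 4 4 88 4
7 4 88 4 4
8 4 4 88 4
9 88 4 4 4
10 4 88 4 4
11 4 4 4 88
12 4 88 4 4
13 88 4 4 4
14 4 4 88 4
15 4 88 4 4
16 88 4 4 4
17 4 4 4 88
18 64 8 8 20
19 88 4 4 4
20 4 88 4 4
21 4 88 4 4
22 4 88 4 4
23 4 88 4 4
24 4 88 4 4
25 88 4 4 4
26 4 4 88 4
27 4 88 4 4
28 88 4 4 4
29 88 4 4 4
30 88 4 4 4
31 88 4 4 4
32 4 4 88 4
33 88 4 4 4
34 4 4 88 4
35 4 4 4 88
36 4 4 4 88
37 4 88 4 4
38 4 4 88 4
39 4 4 4 88
40 4 4 4 88
41 4 4 88 4
42 4 4 88 4
43 88 4 4 4
44 64 8 20 8
45 88 4 4 4
46 4 88 4 4
47 4 4 88 4
48 4 4 88 4
49 4 4 88 4
50 88 4 4 4
51 88 4 4 4
52 4 4 88 4
53 4 4 88 4
54 4 4 4 88
55 4 4 4 88
56 4 88 4 4
57 88 4 4 4
58 4 4 88 4
59 8 20 8 64
60 4 88 4 4
61 4 4 4 88
62 4 4 88 4
63 4 4 4 88
64 20 8 64 8
65 4 4 88 4
66 4 4 4 88
67 88 4 4 4
68 4 4 4 88
69 88 4 4 4
70 4 4 4 88
71 64 8 8 20
72 4 4 4 88
73 4 4 4 88
74 88 4 4 4
75 4 88 4 4
76 88 4 4 4
77 88 4 4 4
78 88 4 4 4
79 4 4 4 88
80 4 4 4 88
81 4 4 88 4
82 4 88 4 4
83 88 4 4 4
84 88 4 4 4
85 88 4 4 4
86 4 88 4 4
87 88 4 4 4
88 88 4 4 4
89 88 4 4 4
90 4 4 4 88
91 88 4 4 4
92 4 88 4 4
93 4 4 88 4
94 20 64 8 8
95 88 4 4 4
96 4 4 4 88
97 88 4 4 4
98 88 4 4 4
99 88 4 4 4
100 4 88 4 4
101 4 4 4 88
102 4 4 88 4
103 4 4 88 4
104 88 4 4 4
105 4 4 4 88
106 88 4 4 4
107 88 4 4 4
108 4 88 4 4
109 88 4 4 4
110 88 4 4 4
111 4 4 4 88
112 4 4 4 88
113 4 4 4 88
114 64 8 20 8
115 4 4 88 4
116 4 4 88 4
117 4 4 88 4
118 4 4 4 88
119 88 4 4 4
120 4 4 88 4
121 88 4 4 4
122 8 20 64 8
123 88 4 4 4
124 4 4 88 4
125 88 4 4 4
126 4 4 4 88
127 4 88 4 4
128 4 88 4 4
129 4 4 88 4
130 4 4 4 88
131 4 88 4 4
132 4 4 88 4
133 88 4 4 4
134 88 4 4 4
135 4 4 4 88
136 8 20 8 64
137 20 8 64 8
138 4 4 4 88
139 88 4 4 4
140 4 4 88 4
141 8 64 20 8
142 4 4 4 88
143 88 4 4 4
144 4 4 88 4
145 4 4 4 88
146 4 88 4 4
147 4 4 4 88
148 20 8 64 8
149 4 4 4 88
150 4 4 88 4
151 4 4 88 4
152 4 4 4 88
153 4 4 4 88
154 8 8 64 20
155 4 4 88 4
156 4 88 4 4
157 4 88 4 4
158 8 20 64 8
159 4 4 88 4
160 4 4 4 88
161 4 88 4 4
162 4 88 4 4
163 4 4 4 88
164 88 4 4 4
165 4 88 4 4
166 4 4 88 4
167 88 4 4 4
168 4 88 4 4
169 88 4 4 4
170 4 4 88 4
171 88 4 4 4
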