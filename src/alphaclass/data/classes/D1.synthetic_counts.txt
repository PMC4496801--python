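>D1 B 171
1 4 4 4 88
2 4 4 4 88
3 4 88 4 4
4 4 4 4 88
5 88 4 4 4
6 4 4 88 4
7 4 88 4 4
8 4 4 88 4
9 88 4 4 4
10 88 4 4 4
11 4 4 4 88
12 4 88 4 4
13 88 4 4 4
14 4 4 88 4
15 4 88 4 4
16 88 4 4 4
17 4 4 4 88
18 64 8 8 20
19 88 4 4 4
20 88 4 4 4
21 4 4 4 88
22 4 88 4 4
23 4 88 4 4
24 88 4 4 4
25 88 4 4 4
26 4 88 4 4
27 4 4 88 4
28 88 4 4 4
29 88 4 4 4
30 88 4 4 4
31 4 4 4 88
32 4 4 88 4
33 88 4 4 4
34 4 4 88 4
35 4 4 4 88
36 4 4 4 88
37 4 88 4 4
38 8 8 64 20
39 4 4 4 88
40 4 4 4 88
41 4 4 88 4
42 4 4 88 4
43 88 4 4 4
44 88 4 4 4
45 88 4 4 4
46 4 88 4 4
47 8 20 64 8
48 4 4 88 4
49 4 4 88 4
50 88 4 4 4
51 64 8 20 8
52 4 4 88 4
53 4 4 4 88
54 20 8 8 64
55 64 8 20 8
56 4 88 4 4
57 4 4 88 4
58 20 8 64 8
59 4 4 4 88
60 4 88 4 4
61 4 4 4 88
62 4 4 88 4
63 4 4 4 88
64 4 4 88 4
65 4 4 4 88
66 4 4 4 88
67 64 20 8 8
68 4 4 4 88
69 88 4 4 4
70 4 4 4 88
71 88 4 4 4
72 4 4 4 88
73 4 4 88 4
74 4 4 4 88
75 4 4 4 88
76 88 4 4 4
77 64 8 20 8
78 88 4 4 4
79 4 4 4 88
80 4 4 88 4
81 4 88 4 4
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
94 4 88 4 4
95 4 4 4 88
96 4 4 4 88
97 88 4 4 4
98 4 88 4 4
99 4 88 4 4
100 4 88 4 4
101 8 20 8 64
102 4 4 88 4
103 4 4 88 4
104 88 4 4 4
105 4 4 4 88
106 8 20 8 64
107 64 8 8 20
108 4 88 4 4
109 64 8 8 20
110 88 4 4 4
111 4 4 4 88
112 4 4 4 88
113 4 4 4 88
114 4 4 88 4
115 4 4 88 4
116 4 88 4 4
117 4 4 88 4
118 4 4 88 4
119 88 4 4 4
120 4 4 88 4
121 88 4 4 4
122 4 4 88 4
123 64 20 8 8
124 4 4 88 4
125 88 4 4 4
126 4 4 4 88
127 4 4 88 4
128 88 4 4 4
129 4 4 88 4
130 4 4 4 88
131 4 4 4 88
132 4 4 88 4
133 88 4 4 4
134 4 4 4 88
135 4 4 4 88
136 4 4 4 88
137 4 4 88 4
138 4 4 4 88
139 4 4 4 88
140 4 4 88 4
141 4 88 4 4
142 4 4 4 88
143 88 4 4 4
144 4 4 88 4
145 4 4 4 88
146 4 88 4 4
147 4 4 4 88
148 4 4 88 4
149 4 4 4 88
150 4 4 88 4
151 4 4 88 4
152 4 88 4 4
153 4 4 4 88
154 88 4 4 4
155 4 4 88 4
156 20 64 8 8
157 4 88 4 4
158 4 88 4 4
159 4 4 88 4
160 88 4 4 4
161 4 88 4 4
162 4 88 4 4
163 4 88 4 4
164 88 4 4 4
165 4 88 4 4
166 4 4 4 88
167 88 4 4 4
168 4 88 4 4
169 4 4 4 88
170 4 4 88 4
171 4 4 4 88
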