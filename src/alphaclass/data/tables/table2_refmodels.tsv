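idx	chroms	accession	size_bp	sf	state	hor_symbol	misassembled
1	chr1	GJ211836.1	198076	3			no
2	chr1	GJ211837.1	278512	3			no
3	chr1	GJ211855.1	63597	3			no
4	chr1	GJ211857.1	83495	3			no
5	chr1,5,19	GJ212202.1	2282185	1	live	D1Z7/D5Z2/D19Z3	no
6	chr2	GJ211860.1	1902412	2	live	D2Z1	no
7	chr3	GJ211866.1	461128	1,5			no
8	chr3	GJ211867.1	13936	1,5			no
9	chr3	GJ211871.1	2102155	1	live	D3Z1	no
10	chr4	GJ211881.1	2031890	2	live	D4Z1	no
11	chr5	GJ211882.1	83162	5			yes
12	chr5	GJ211883.1	227563	5			no
13	chr5	GJ211884.1	264463	5			no
14	chr5	GJ211886.1	46345	5			no
15	chr5	GJ211887.1	142630	1			no
16	chr5,19	GJ211904.2	53672	5			no
17	chr5,19	GJ211906.2	338504	5			no
18	chr6	GJ211907.1	1276046	1	live	D6Z1	no
19	chr7	GJ211908.1	2658581	1	live	D7Z1	no
20	chr7	GJ212194.1	150232	5			no
21	chr8	GJ211909.1	1843521	2	live	D8Z2	no
22	chr9	GJ211929.1	2128923	2	live	D9Z4	no
23	chr10	GJ211930.1	249218	1			no
24	chr10	GJ211932.1	1561440	1	live	D10Z1	no
25	chr10	GJ211933.1	48180	1			no
26	chr10	GJ211936.1	47701	1			no
27	chr11	GJ211938.1	11969	5			no
28	chr11	GJ211943.1	3251982	3	live	D11Z1	no
29	chr11	GJ211948.1	82575	3			no
30	chr12	GJ211949.1	47204	1			no
31	chr12	GJ211954.1	2349957	1	live	D12Z3	no
32	chr13,14,21,22	GJ211955.2	22537	4+			no
33	chr13,14,21,22	GJ211961.2	88022	4+			no
34	chr13,14,21,22	GJ211962.2	54133	4+			no
35	chr13,14,21,22	GJ211963.2	63535	4+			yes
36	chr13,14,21,22	GJ211965.2	20670	5			no
37	chr13,14,21,22	GJ211967.2	6670	4+			no
38	chr13,14,21,22	GJ211968.2	3245	4+			no
39	chr13,14,21,22	GJ211969.2	22561	4+			no
40	chr13,14,21,22	GJ211972.2	1134211	2	live	D14Z9/D22Z?	no
41	chr13,14,21,22	GJ211986.2	1198	4+			no
42	chr13,14,21,22	GJ211991.2	632586	2	live	D13Z1/D21Z1	no
43	chr13,14,21,22	GJ212205.1	340	1			no
44	chr13,14,21,22	GJ212206.1	340	1			no
45	chr15	GJ212036.1	415278	4+			no
46	chr15	GJ212042.1	855957	4+			no
47	chr15	GJ212045.1	1370146	2	live	D15Z3	no
48	chr16	GJ212046.1	23302	2			no
49	chr16	GJ212051.1	1928003	1	live	D16Z2	no
50	chr17	GJ212053.1	381239	3			no
51	chr17	GJ212054.1	3371615	3	live	D17Z1	yes
52	chr17	GJ212055.1	49431	3			no
53	chr18	GJ212060.1	319478	2			no
54	chr18	GJ212062.1	4763584	2	live	D18Z1	no
55	chr18	GJ212066.1	93042	2			no
56	chr18	GJ212067.1	39636	2			no
57	chr18	GJ212069.1	76958	2			no
58	chr18	GJ212071.1	21409	2			yes
59	chr20	GJ212091.1	150723	2			no
60	chr20	GJ212093.1	1886394	2	live	D20Z2	no
61	chr20	GJ212095.1	47956	2,5			no
62	chr20	GJ212105.1	80766	4+			no
63	chr20	GJ212107.1	78875	4+			yes
64	chr20	GJ212117.1	120944	5			no
65	chrX	GJ212192.1	3806963	3	live	DXZ1	no
66	chrY	GJ212193.1	227095	4+	live	DYZ3	no
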