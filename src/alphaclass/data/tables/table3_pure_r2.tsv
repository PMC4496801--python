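sf	location	position_hg38	contigs	size_bp	r2_pct	bbox_pct	hor_call
SF5	6q11.1	chr6:61326977-61336104	AMYH02013791.1	9127	78	2	No HOR
SF5	6q11.1	chr6:61428794-61437937	FP325349.3	9143	78	2	No HOR
SF5	7p11.2	chr7:57939175-57953728	AC138789.1	10294	94	0	No HOR
SF5	7q11.21	chr7:62536194-62564614	AC019063.4	24011	83	2	No HOR
SF5	10p11.1	chr10:39432620-39442102	ABBA01020709.1	6981	70	0	No HOR
SF5	11p11.12	chr11:48806070-48814307	AC127495.2	8237	91	0	No HOR
SF5	12q11	chr12:37632794-37639361	AC119042.9	6567	75	0	No HOR
SF5	16p11.1	chr16:36001814-36022913	AC109490.3	21099	94	0	No HOR, duplication 4.8 kb, identity 97.5%
SF5	16p11.1	chr16:36079689-36090000	FP325312.10	10311	93	0	No HOR
SF5	20q11.1	chr20:29908640-30038347	ABBA01018540.1,GJ212117.1	128442	80	0	HOR 1.4 kb
SF5	20q11.1	chr20:30088752-30140826	FP565326.9	51870	83	0	HOR 1.4 kb
SF5	Xq11.1	chrX:62611837-62642074	BX544875.1	30237	90	3	No HOR
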