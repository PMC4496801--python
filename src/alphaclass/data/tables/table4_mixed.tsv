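sf	location	position_hg38	contigs	size_bp	sf1_pct	sf2_pct	sf5_pct	hor_call
SF2/SF5	2q21.2	chr2:132237392-132247263	AC097532.3	9871	0	22	58	No HOR
SF1/SF5	3p11.1	chr3:90482385-90722299	ABBA01004652.1,AEKP01209350.1,ABBA01004653.1,AEKP01209353.1,ABBA01004654.1,ABBA01004655.1,ABBA01004656.1	229441	40	0	41	No HOR
SF1/SF5	3p11.1 3q11.1	chr3:90772554-91233510	GJ211866.1	460956	48	0	35	HOR 1.7 kb
SF1/SF5	3q11.1	chr3:91233782-91247547	GJ211867.1	13765	57	0	31	No HOR other than AB dimer, identity ~93%
SF1/SF5	3q11.1	chr3:91247775-91286183	ABBA01000927.1,ABBA01000928.1,ABBA01000929.1,ABBA01000930.1,ABBA01000931.1	17430	50	0	32	HOR 1.7 kb
SF1/SF5	3q11.1	chr3:93716246-93725946	ABBA01026974.1	9700	35	0	49	No HOR
SF1/SF5	6q11.1	chr6:60230028-60241613	AC244258.2	11401	28	0	53	No HOR
SF1/SF5	6q11.1	chr6:61371445-61427364	AEKP01189806.1,AEKP01189805.1,AEKP01189804.1,AEKP01189803.1,AEKP01189802.1,FP325349.3	55519	30	0	57	No HOR
SF2/SF5	7q11.1	chr7:61096433-61103082	AC142121.2,AC017075.8	6649	0	38	46	No HOR
SF1/SF5	8p11.1	chr8:43940231-43965733	AC127507.4,AC144576.3	22886	15	0	74	No HOR
SF1/SF5	8q11.1	chr8:45946092-45971262	AC118650.5	22549	16	0	70	No HOR
SF2/SF5	9p11.2	chr9:40556928-40565104	AMYH02020868.1,FP325318.4	7524	0	40	46	No HOR
SF2/SF5	9p11.2	chr9:40862745-40873147	AL353626.5	10402	0	28	50	No HOR
SF1/SF5	10p11.1	chr10:39548571-39555979	ABBA01020707.1	7408	35	0	52	No HOR
SF1/SF5	12p11.1	chr12:34686342-34715037	AC144535.4,AUXG01000432.1	28658	60	0	30	No HOR
SF2/SF5	16p11.2	chr16:34219066-34252724	AC136932.4,ABBA01017803.1	30263	0	35	36	No HOR
SF2/SF5	20q11.1	chr20:28509094-28556877	GJ212095.1	47783	0	27	54	HOR 1.9 kb
SF2/SF5	22q11.1	chr22:15965313-15972300	AC145543.3	6987	0	41	34	No HOR
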