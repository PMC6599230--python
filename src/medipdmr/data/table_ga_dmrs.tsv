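DMR Location	DMR Width	baseMean	log2 FoldChange	padj	Annotation	Nearest Gene
chr11:1069274-1070940	1666	275.32	-0.077895692	0.000669	Distal Intergenic	MUC2
chr7:158509261-158511170	1909	785.4202	-0.055129353	0.001379	Distal Intergenic	NCAPG2
chr8:143302532-143305491	2959	708.6988	-0.057666861	0.001379	Intron	LINC00051
chr11:51578780-51581392	2612	5862.829	0.12089555	0.007632	Distal Intergenic	OR4C46
chr15:22741828-22744210	2382	1025.047	-0.091557436	0.007632	Exon	GOLGA6L1
chr17:21901995-21907966	5971	1435.135	0.114589697	0.008451	Promoter (<=1 kb)	FLJ36000
chr11:51587551-51593541	5990	6613.759	0.114797282	0.012877	Distal Intergenic	OR4C46
chr10:115540476-115542108	1632	369.5293	-0.058238042	0.015459	Promoter (2-3 kb)	MIR4483
chr4:9875-10674	799	300.733	-0.066430834	0.020835	Distal Intergenic	ZNF595
chr5:49415136-49417649	2513	629.6273	0.098693759	0.020835	Distal Intergenic	EMB
chr15:56071747-56073363	1616	280.2815	-0.044766281	0.028409	Distal Intergenic	PRTG
chrY:59027085-59033404	6319	757.9891	0.085296918	0.028937	Distal Intergenic	SPRY3
chr10:127579482-127584720	5238	732.2817	0.072848407	0.032657	Promoter (<=1 kb)	DHX32
chr10:134878560-134880844	2284	289.1369	-0.080610086	0.032657	Distal Intergenic	ADGRA1
chr11:1795935-1798177	2242	452.7534	-0.059025405	0.032657	Distal Intergenic	MOB2
chr11:51570928-51573041	2113	623.7097	0.10472301	0.032657	Distal Intergenic	OR4C46
chr11:51581774-51585209	3435	3634.642	0.099090126	0.032657	Distal Intergenic	OR4C46
chr19:24622360-24624613	2253	338.0393	0.100239042	0.032657	Distal Intergenic	HAVCR1P1
chr2:60693762-60695701	1939	293.8868	-0.074300347	0.032657	Intron	BCL11A
chr2:90374619-90378951	4332	2470.989	0.08904097	0.032657	Intron	MIR4436A
chr2:92280419-92282186	1767	1109.498	0.085845619	0.032657	Distal Intergenic	ACTR3BP2
chr21:11121793-11128301	6508	1510.744	0.043743747	0.032657	Distal Intergenic	BAGE
chr5:49413369-49415026	1657	555.3467	0.102896519	0.032657	Distal Intergenic	EMB
chr6:58775746-58780286	4540	59219.18	0.088992793	0.032657	Distal Intergenic	GUSBP4
chr6:132921367-132922856	1489	702.8588	-0.077101273	0.032657	Distal Intergenic	TAAR3
chr7:155125413-155128850	3437	1162.764	-0.038748136	0.032657	Distal Intergenic	INSIG1
chr7:155199140-155201882	2742	355.5753	-0.077494132	0.032657	Distal Intergenic	EN2
chr2:91603906-91606341	2435	1002.445	0.094259612	0.033077	Distal Intergenic	LOC654342
chr1:16888159-16896002	7843	1691.305	0.055571393	0.035079	3′ UTR	MIR3675
chr2:91595932-91600986	5054	2660.109	0.085847679	0.035079	Distal Intergenic	LOC654342
chr5:49428377-49432607	4230	1837.6	0.094529868	0.035079	Distal Intergenic	EMB
chr5:49434812-49441568	6756	3582.595	0.092033374	0.035079	Distal Intergenic	EMB
chr8:143093456-143095020	1564	434.2594	-0.048625159	0.037056	Distal Intergenic	MIR4472-1
chr9:43157894-43160792	2898	440.6311	-0.051599615	0.038038	Distal Intergenic	LOC642929
chr3:196625149-196626329	1180	5459.852	0.091127805	0.03925	Intron	SENP5
chr1:2775172-2776643	1471	300.3145	-0.049869539	0.043507	Distal Intergenic	TTC34
chr1:161411315-161417356	6041	980.0181	0.059054185	0.043507	Exon	FCGR2A
chr1:227165108-227167121	2013	321.0379	-0.05472419	0.043507	Promoter (<=1 kb)	ADCK3
chr10:42639382-42642799	3417	471.9378	0.053591881	0.043507	Distal Intergenic	LOC441666
chr12:117759233-117761187	1954	733.3737	-0.051097394	0.043507	Intron	NOS1
chr12:131743021-131745096	2075	402.1728	-0.04241032	0.043507	Distal Intergenic	LINC01257
chr14:104680716-104682479	1763	393.9317	-0.039036454	0.043507	Distal Intergenic	KIF26A
chr14:106130890-106133431	2541	327.5869	-0.050328469	0.043507	Intron	ELK2AP
chr18:9876-11028	1152	869.3626	-0.058790034	0.043507	Distal Intergenic	ROCK1P1
chr2:90380982-90382232	1250	703.058	0.087608099	0.043507	Intron	MIR4436A
chr2:90390888-90393740	2852	1224.857	0.082639282	0.043507	Intron	MIR4436A
chr2:232245135-232247014	1879	684.5341	-0.049273959	0.043507	Distal Intergenic	B3GNT7
chr2:233878888-233880783	1895	458.8731	-0.042533652	0.043507	Promoter (<=1 kb)	NGEF
chr21:47233703-47236436	2733	660.0114	-0.045879449	0.043507	Intron	LOC100129027
chr22:28043663-28045838	2175	319.4394	-0.045382128	0.043507	Distal Intergenic	MN1
chr3:185842547-185844972	2425	338.0063	-0.040820001	0.043507	Distal Intergenic	ETV5
chr4:3679282-3681125	1843	632.2126	-0.039394589	0.043507	Promoter (<=1 kb)	LOC100133461
chr5:171997237-171998674	1437	574.0105	-0.040752286	0.043507	Distal Intergenic	NEURL1B
chr5:172145042-172146642	1600	283.15	-0.039405643	0.043507	Distal Intergenic	DUSP1
chr7:35083300-35086409	3109	667.0347	-0.063938851	0.043507	Exon	DPY19L1
chr8:27426562-27428394	1832	618.5586	-0.046453345	0.043507	Distal Intergenic	CLU
chrX:148615982-148617887	1905	496.8346	-0.071187463	0.043507	Promoter (<=1 kb)	IDS
chr14:77322208-77324017	1809	358.4726	-0.036853715	0.043857	Exon	LRRC74A
chr14:94213175-94214970	1795	274.9046	-0.044559973	0.043963	Intron	PRIMA1
chr8:143824284-143827190	2906	872.6112	-0.056328342	0.043963	Promoter (<=1 kb)	SLURP1
chr2:92289472-92292822	3350	4738.836	0.085456146	0.04533	Distal Intergenic	ACTR3BP2
chr1:15170988-15172589	1601	341.8562	-0.043070132	0.045985	Intron	KAZN
chr1:22873178-22875162	1984	628.9255	-0.048195935	0.045985	Distal Intergenic	EPHA8
chr15:32781660-32783301	1641	391.2485	-0.044570446	0.045985	Distal Intergenic	GOLGA8O
chr2:92294963-92300499	5536	4633.964	0.085605878	0.048908	Distal Intergenic	ACTR3BP2
chr4:5852906-5854271	1365	315.8726	-0.042689188	0.048908	Exon	CRMP1
chr7:15223273-15225157	1884	555.7869	-0.050035386	0.048908	Distal Intergenic	DGKB
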