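DMR Location	DMR Width	baseMean	log2 FoldChange	padj	Annotation	Nearest Gene
chr10:1281019-1282852	1833	614.6687	-1.39475	0.001099	Intron	ADARB2
chr22:29515430-29517126	1696	2125.015	-0.7487	0.001099	Intron	KREMEN1
chr2:60693762-60695701	1939	293.8868	-0.96653	0.003059	Intron	BCL11A
chr1:16888159-16896002	7843	1691.305	0.664717	0.018052	3′ UTR	MIR3675
chr15:22741828-22744210	2382	1025.047	-1.02204	0.018052	Exon	GOLGA6L1
chr15:32781660-32783301	1641	391.2485	-0.56857	0.018052	Distal Intergenic	GOLGA8O
chr17:21901995-21907966	5971	1435.135	1.262002	0.018052	Promoter (<=1 kb)	FLJ36000
chr19:24622360-24624613	2253	338.0393	1.234145	0.018052	Distal Intergenic	HAVCR1P1
chr19:37783156-37788148	4992	786.5645	1.768082	0.018052	Distal Intergenic	HKR1
chr2:92280419-92282186	1767	1109.498	1.027544	0.018052	Distal Intergenic	ACTR3BP2
chr20:20317316-20318796	1480	713.2818	-0.66627	0.018052	Intron	INSM1
chr9:73946028-73947394	1366	290.2041	-0.64868	0.024388	Intron	TRPM3
chr18:15404549-15410901	6352	972.9929	1.687868	0.02956	Distal Intergenic	LOC644669
chr2:92289472-92292822	3350	4738.836	1.060257	0.032703	Distal Intergenic	ACTR3BP2
chr1:16932177-16936537	4360	710.057	0.489202	0.048809	5′ UTR	NBPF1
chr2:90371419-90374495	3076	1492.051	1.021356	0.048809	Intron	MIR4436A
chr2:90374619-90378951	4332	2470.989	1.010006	0.048809	Intron	MIR4436A
chr2:91595932-91600986	5054	2660.109	0.993924	0.048809	Distal Intergenic	LOC654342
chr5:180899895-180903257	3362	290.8312	0.778464	0.048809	Distal Intergenic	OR4F16
chr7:158998336-159000338	2002	314.5755	-0.72705	0.048809	Distal Intergenic	VIPR2
chr8:43792848-43795213	2365	1959.954	1.112517	0.048809	Distal Intergenic	POTEA
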