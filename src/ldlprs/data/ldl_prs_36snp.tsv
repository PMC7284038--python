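rsid	chrom	pos	other_allele	effect_allele	weight	gene	q1	pvalue
rs629301	1	109275684	G	T	0.1736	CELSR2	Yes	1E-170
rs4420638	19	44919689	A	G	0.2153	APOC1	No	9E-147
rs6511720	19	11091630	T	G	0.2108	LDLR	Yes	4E-117
rs1367117	2	21041028	G	A	0.1307	APOB	Yes	4E-114
rs515135	2	21063185	T	C	0.1458	-	No	3E-109
rs1531517	19	44738916	A	G	0.2482	-	No	4E-99
rs395908	19	44870308	A	G	0.1512	NECTIN2	No	1E-89
rs7254892	19	44886339	A	G	0.4181	TOMM40	No	3E-89
rs12721109	19	44943964	A	G	0.452	APOC4	No	1E-72
rs10402271	19	44825957	T	G	0.0916	BCAM	No	6E-63
rs4299376	2	43845437	T	G	0.0812	ABCG8	Yes	2E-47
rs12916	5	75360714	T	C	0.0755	HMGCR	No	5E-45
rs6859	19	44878777	G	A	0.0775	NECTIN2	No	6E-37
rs5930	19	11113589	A	G	0.0649	LDLR	No	3E-33
rs4953023	2	43846861	A	G	0.1347	ABCG8	No	3E-33
rs405509	19	44905579	G	T	0.0754	APOE	No	1E-31
rs2287029	19	10806008	T	C	0.0786	DNM2	No	4E-31
rs6725189	2	20996129	T	G	0.0713	AC115619.1	No	5E-30
rs2980875	8	125469505	G	A	0.0578	AC091114.1	No	3E-29
rs2479409	1	55038977	A	G	0.0671	PCSK9	Yes	2E-28
rs11685356	2	20974287	C	T	0.0668	-	No	2E-27
rs1529729	19	11052886	T	C	0.0533	SMARCA4	No	2E-25
rs6547409	2	20967337	T	C	0.1525	-	No	3E-25
rs12127701	1	109295642	G	A	0.126	MYBPHL	No	1E-24
rs253412	5	75660016	A	G	0.0559	ANKDD1B	No	1E-24
rs16979372	19	44692043	G	T	0.1499	AC243964.2	No	4E-24
rs413582	1	109308504	C	T	0.0518	MYBPHL	No	2E-23
rs2000999	16	72074194	G	A	0.0636	HPR	No	2E-22
rs6882076	5	156963286	T	C	0.0536	TIMD4	No	2E-22
rs287227	1	55190402	T	G	0.0753	USP24	No	2E-22
rs10401969	19	19296909	T	C	0.106	SUGP1	No	7E-22
rs649129	9	133278860	T	C	0.0607	ABO	No	8E-22
rs174583	11	61842278	T	C	0.0511	FADS2	No	1E-21
rs1004165	19	44728939	G	A	0.0566	RF00285	No	4E-21
rs16996148	19	19547663	T	G	0.0877	CILP2	No	6E-21
rs10198175	2	20934123	G	A	0.0864	-	No	7E-21
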