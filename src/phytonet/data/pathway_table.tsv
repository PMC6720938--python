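rank	pathway_name	common_genes	nr	pct_associated	p_value
1	Steroid hormone biosynthesis	CYP19A1,CYP1A1,CYP1A2,HSD11B1,HSD11B2,HSD17B1,HSD17B2	7	12.07	9.17e-9
2	Tyrosine metabolism	ALDH1A3,MAOA,MAOB,MIF,TYR	5	14.29	6.05e-7
3	Phenylalanine metabolism	ALDH1A3,MAOA,MAOB,MIF	4	23.53	1.08e-6
4	Ovarian steroidogenesis	ALOX5,CYP19A1,CYP1A1,HSD17B1,HSD17B2	5	10.00	3.74e-6
5	Arginine and proline metabolism	MAOA,MAOB,NOS1,NOS2,NOS3	5	10.00	3.74e-6
6	Arachidonic acid metabolism	ALOX12B,ALOX15,ALOX15B,ALOX5,CBR3	5	8.06	1.10e-5
7	Serotonergic synapse	ALOX12B,ALOX15,ALOX15B,ALOX5,MAOA,MAOB	6	5.31	1.52e-5
8	Metabolism of xenobiotics by cytochrome P450	ALDH1A3,CBR3,CYP1A1,CYP1A2,HSD11B1	5	6.76	2.61e-5
9	Tryptophan metabolism	CYP1A1,CYP1A2,MAOA,MAOB	4	10.00	3.82e-5
10	Arginine biosynthesis	NOS1,NOS2,NOS3	3	14.29	1.32e-4
11	Histidine metabolism	ALDH1A3,MAOA,MAOB	3	12.50	1.99e-4
12	Retinol metabolism	ALDH1A1,CYP1A1,CYP1A2,RDH8	4	6.15	2.59e-4
13	p53 signaling pathway	CCNB3,CDK1,CDK2,CDK6	4	5.80	3.26e-4
14	Drug metabolism	ALDH1A3,CYP1A2,MAOA,MAOB	4	5.71	3.45e-4
15	Chemical carcinogenesis	ALDH1A3,CYP1A1,CYP1A2,HSD11B1	4	4.88	6.31e-4
16	ABC transporters	ABCB1,ABCB4,ABCG2	3	6.67	1.30e-3
17	Bile secretion	ABCB1,ABCB4,ABCG2	3	4.23	4.80e-3
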