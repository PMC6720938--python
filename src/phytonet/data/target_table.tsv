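uniprot_id	protein_name	betweenness	degree	gene_name
P14174	Macrophage migration inhibitory factor	0.0743	63	MIF
P27338	Amine oxidase [flavin-containing] B	0.0743	63	MAOB
P10275	Androgen receptor	0.0688	61	AR
Q92731	Estrogen receptor beta	0.0606	59	ESR2
P15121	Aldose reductase	0.0563	57	AKR1B1
O14977	Antizyme inhibitor protein	0.0483	53	AZIN1
P22303	Acetylcholinesterase	0.0437	52	ACHE
P03372	Estrogen receptor	0.0400	50	ESR1
P14061	Estradiol 17-beta-dehydrogenase 1	0.0384	49	HSD17B1
Q96JD6	1,5-anhydro-D-fructose reductase	0.0271	41	AKR1E2
Q9NYR8	Retinol dehydrogenase 8	0.0211	37	RDH8
P29274	Adenosine receptor A2a	0.0170	33	ADORA2A
O75891	Cytosolic 10-formyltetrahydrofolate dehydrogenase	0.0167	33	ALDH1L1
P47895	Aldehyde dehydrogenase family 1 member A3	0.0101	26	ALDH1A3
P05177	Cytochrome P450 1A2	0.0094	25	CYP1A2
C9JRZ8	Aldo-keto reductase family 1 member B15	0.0089	25	AKR1B15
P14550	Alcohol dehydrogenase [NADP(+)]	0.0088	24	AKR1A1
P04798	Cytochrome P450 1A1	0.0048	18	CYP1A1
P28845	Corticosteroid 11-beta-dehydrogenase isozyme 1	0.0044	17	HSD11B1
P09917	Arachidonate 5-lipoxygenase	0.0040	17	ALOX5
O75342	Arachidonate 12-lipoxygenase	0.0038	16	ALOX12B
P16050	Arachidonate 15-lipoxygenase	0.0038	15	ALOX15
P30542	Adenosine receptor A1	0.0032	15	ADORA1
O15296	Arachidonate 15-lipoxygenase B	0.0028	15	ALOX15B
P06493	Cyclin-dependent kinase 1	0.0028	14	CDK1
Q00534	Cyclin-dependent kinase 6	0.0025	14	CDK6
P11511	Cytochrome P450 19A1	0.0024	13	CYP19A1
Q06124	Tyrosine-protein phosphatase non-receptor type 11	0.0021	12	PTPN11
P21397	Amine oxidase [flavin-containing] A	0.0015	11	MAOA
P80365	Corticosteroid 11-beta-dehydrogenase isozyme 2	0.0015	11	HSD11B2
Q13627	Dual specificity tyrosine-phosphorylation-regulated kinase 1A	0.0013	10	DYRK1A
Q8WWL7	G2/mitotic-specific cyclin-B3	0.0010	8	CCNB3
Q00526	Cyclin-dependent kinase 3	0.0008	7	CDK3
P35228	Nitric oxide synthase	0.0006	7	NOS2
Q9NPH5	NADPH oxidase 4	0.0006	7	NOX4
Q7Z5J1	Hydroxysteroid 11-beta-dehydrogenase 1-like protein	0.0005	7	HSD11B1L
P0DMS8	Adenosine receptor A3	0.0005	6	ADORA3
P29474	Nitric oxide synthase, endothelial	0.0006	6	NOS3
P29475	Nitric oxide synthase, brain	0.0006	6	NOS1
P24941	Cyclin-dependent kinase 2	0.0004	6	CDK2
P06276	Cholinesterase	0.0003	5	BCHE
O75828	Carbonyl reductase [NADPH] 3	0.0002	4	CBR3
P37059	Estradiol 17-beta-dehydrogenase 2	0.0002	3	HSD17B2
Q9UNQ0	ATP-binding cassette sub-family G member 2	0.0001	3	ABCG2
P00352	Retinal dehydrogenase 1	0.0001	2	ALDH1A1
P21439	Multidrug resistance protein 3	0.0000	2	ABCB4
P47989	Xanthine dehydrogenase/oxidase	0.0000	2	XDH
P14679	Tyrosinase	0.0000	2	TYR
P08183	Multidrug resistance protein 1	0.0000	1	ABCB1
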