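c. Notation	p. Notation	Variant Type	ACMG Classification August 2023	ACMG Classification October 2024	Source	Wild-Type Construct	Acceptor Gain	Acceptor Loss	Donor Gain	Donor Loss	Acceptor Gain Position	Acceptor Loss Position	Donor Gain Position	Donor Loss Position
c.12G>T	p.(Gln4His)	Missense	VUS	VUS	ClinVar	WT-1	0.31	0.03	0.00	0.04	68	0	−1662	−82
c.252C>A	p.(Ile84=)	Synonymous	VUS	VUS	ClinVar	WT-2	0.00	0.25	0.00	0.18	−346	6	57	−101
c.254G>A	p.(Arg85His)	Missense	VUS	LP	ClinVar	WT-2	0.00	0.13	0.00	0.07	−344	8	8	−99
c.259G>A	p.(Asp87Asn)	Missense	VUS	VUS	LOVD	WT-2	0.00	0.25	0.00	0.19	−339	13	64	−94
c.260A>G	p.(Asp87Gly)	Missense	VUS	LP	ClinVar	WT-2	0.00	0.12	0.00	0.04	−338	14	1	−93
c.267C>T	p.(Tyr89=)	Synonymous	LB	LB	ClinVar	WT-2	0.00	0.15	0.00	0.10	−331	21	−4009	−86
c.268G>A	p.(Val90Ile)	Missense	VUS	VUS	ClinVar	WT-2	0.00	0.16	0.00	0.08	−330	22	73	−85
c.283G>C	p.(Glu95Gln)	Missense	VUS	LP	ClinVar	WT-2	0.00	0.14	0.00	0.06	−3	37	2014	−70
c.291G>A	p.(Arg97=)	Synonymous	LB	LB	ClinVar	WT-2	0.00	0.11	0.00	0.08	−307	45	−3985	−62
c.292A>G	p.(Ile98Val)	Missense	VUS	VUS	ClinVar	WT-2	0.00	0.27	0.00	0.25	−306	46	−3984	−61
c.294C>A	p.(Ile98=)	Synonymous	VUS	VUS	ClinVar	WT-2	0.00	0.37	0.00	0.46	1997	48	99	−59
c.294C>T	p.(Ile98=)	Synonymous	VUS	VUS	ClinVar	WT-2	0.00	0.27	0.00	0.25	−304	48	99	−59
c.297C>T	p.(Val99=)	Synonymous	LB	LB	ClinVar	WT-2	0.00	0.23	0.00	0.19	−301	51	102	−56
c.304G>A	p.(Glu102Lys)	Missense	VUS	LP	LOVD	WT-2	0.00	0.23	0.00	0.21	−294	58	2035	−49
c.353+4A>T	p.(?)	NCSS	VUS	VUS	ClinVar	WT-2	0.00	0.26	0.00	0.22	−162	111	−17	4
c.354G>T	p.(Arg118Ser)	Missense	VUS	LP	LOVD	WT-2	0.01	0.73	0.00	0.66	−20	0	−1480	−141
c.371G>A	p.(Arg124Gln)	Missense	VUS	VUS	ClinVar	WT-2	0.03	0.13	0.00	0.11	−3	17	−3	−124
c.375A>G	p.(Gly125=)	Synonymous	VUS	VUS	ClinVar	WT-2	0.00	0.24	0.00	0.20	−120	21	0	−120
c.408C>T	p.(Val136=)	Synonymous	LB	LB	ClinVar	WT-2	0.01	0.13	0.00	0.11	−8	54	1225	−87
c.417G>A	p.(Val139=)	Synonymous	VUS	VUS	ClinVar	WT-2	0.04	0.20	0.00	0.13	1	63	−2	−78
c.425A>G	p.(Asp142Gly)	Missense	VUS	VUS	LOVD	WT-2	0.00	0.21	0.00	0.16	−70	71	1	−70
c.425A>T	p.(Asp142Val)	Missense	VUS	VUS	ClinVar	WT-2	0.00	0.15	0.00	0.12	−70	71	1242	−70
c.447C>A	p.(Thr149=)	Synonymous	LB	LB	ClinVar	WT-2	0.00	0.14	0.00	0.11	−48	93	−967	−48
c.447C>T	p.(Thr149=)	Synonymous	LB	LB	ClinVar	WT-2	0.00	0.24	0.00	0.17	−26	93	−1387	−48
c.450C>T	p.(Asn150=)	Synonymous	LB	LB	ClinVar	WT-2	0.00	0.15	0.00	0.11	−45	96	1267	−45
c.494A>T	p.(Gln165Leu)	Missense	VUS	VUS	ClinVar	WT-2	0.00	0.58	0.21	0.83	1698	140	−18	−1
c.576T>A	p.(Ile192=)	Synonymous	VUS	LB	ClinVar	WT-2	0.14	0.14	0.11	0.15	−2	80	−1	−67
c.612C>T	p.(Tyr204=)	Synonymous	LB	LB	ClinVar	WT-2	0.02	0.11	0.02	0.12	404	116	35	−31
c.643+5G>A	p.(?)	NCSS	VUS	VUS	ClinVar	WT-3	0.00	0.42	0.06	0.42	5	152	71	5
c.644–14C>G	p.(?)	NCSS	VUS	VUS	ClinVar	WT-3	0.01	0.32	0.00	0.24	1632	−14	1197	−95
c.644–5T>A	p.(?)	NCSS	VUS	VUS	ClinVar	WT-3	0.02	0.42	0.01	0.33	1641	−5	1206	−86
c.644–9T>G	p.(?)	Missense	VUS	VUS	ClinVar	WT-3	0.00	0.18	0.00	0.18	1637	−9	1202	−90
c.650A>T	p.(Glu217Val)	Missense	VUS	VUS	ClinVar	WT-3	0.01	0.40	0.01	0.31	−1320	6	1217	−75
c.652G>T	p.(Asp218Tyr)	Missense	VUS	VUS	ClinVar	WT-3	0.01	0.31	0.00	0.23	1654	8	1219	−73
c.675C>G	p.(Ile225Met)	Missense	LB	B	LOVD	WT-3	0.00	0.17	0.00	0.14	−288	31	1242	−50
c.675C>T	p.(Ile225=)	Synonymous	VUS	VUS	ClinVar	WT-3	0.00	0.27	0.00	0.20	1677	31	1242	−50
c.676G>A	p.(Val226Ile)	Missense	VUS	VUS	LOVD	WT-3	0.00	0.25	0.00	0.18	1390	32	1243	−49
c.676G>T	p.(Val226Phe)	Missense	VUS	VUS	ClinVar	WT-3	0.00	0.29	0.00	0.22	1678	32	1243	−49
c.701G>A	p.(Arg234Gln)	Missense	VUS	VUS	ClinVar	WT-3	0.00	0.21	0.00	0.19	−25	57	1268	−24
c.708G>A	p.(Lys236=)	Synonymous	LB	VUS	ClinVar	WT-3	0.01	0.22	0.00	0.19	−18	64	−147	−17
c.713C>G	p.(Ser238Cys)	Missense	VUS	VUS	LOVD	WT-3	0.00	0.25	0.00	0.22	1715	69	1280	−12
c.717C>T	p.(Tyr239=)	Synonymous	LB	LB	ClinVar	WT-3	0.01	0.18	0.00	0.16	−9	73	1284	−8
c.718G>T	p.(Val240Phe)	Missense	VUS	LP	ClinVar	WT-3	0.01	0.14	0.00	0.10	−8	74	1285	−7
c.722A>G	p.(His241Arg)	Missense	VUS	LP	ClinVar	WT-3	0.00	0.07	0.03	0.12	1724	78	1	−3
c.725+4A>G	p.(?)	NCSS	VUS	VUS	LOVD	WT-3	0.01	0.39	0.00	0.33	1731	85	1655	4
c.725+6T>C	p.(?)	NCSS	VUS	VUS	ClinVar	WT-3	0.00	0.20	0.00	0.19	5	87	1657	6
c.725+9A>G	p.(?)	NCSS	LB	LB	ClinVar	WT-3	0.00	0.12	0.00	0.09	8	90	−121	9
c.726–3C>A	p.(?)	NCSS	VUS	VUS	LOVD	WT-3	0.07	0.81	0.00	0.36	100	−3	100	−135
c.858+4A>G	p.(?)	NCSS	VUS	VUS	ClinVar	WT-3	0.00	0.43	0.00	0.26	479	136	0	4
c.998G>A	p.(Gly333Glu)	Missense	VUS	LP	ClinVar	WT-3	0.01	0.31	0.16	0.39	700	−626	−155	0
c.999–3C>G	p.(?)	NCSS	VUS	VUS	ClinVar	WT-3	0.01	0.76	0.00	0.65	−188	−3	65	−132
c.1020C>T	p.(Tyr340=)	Synonymous	LB	LB	ClinVar	WT-3	0.12	0.15	0.00	0.09	−11	21	89	−108
c.1031C>T	p.(Ala344Val)	Missense	VUS	VUS	ClinVar	WT-3	0.00	0.12	0.00	0.09	−153	32	32	−97
c.1034A>G	p.(Asn345Ser)	Missense	VUS	VUS	ClinVar	WT-3	0.01	0.14	0.00	0.09	3	35	103	−94
c.1040G>T	p.(Arg347Leu)	Missense	VUS	LP	ClinVar	WT-3	0.00	0.10	0.00	0.11	−144	41	41	−88
c.1053A>G	p.(Glu351=)	Synonymous	VUS	VUS	ClinVar	WT-3	0.00	0.14	0.00	0.10	−131	54	14	−75
c.1058T>G	p.(Val353Gly)	Missense	VUS	VUS	ClinVar	WT-3	0.00	0.28	0.00	0.20	−126	59	824	−70
c.1092A>G	p.(Glu364=)	Synonymous	VUS	VUS	ClinVar	WT-3	0.01	0.33	0.22	0.41	−92	93	0	−36
c.1118A>G	p.(Asn373Ser)	Missense	VUS	VUS	ClinVar	WT-3	0.00	0.18	0.00	0.16	−66	119	187	−10
c.1125C>T	p.(Asp375=)	Synonymous	LB	LB	ClinVar	WT-3	0.00	0.11	0.01	0.08	−59	126	33	−3
c.1244–17T>A	p.(?)	NCSS	LB	LB	ClinVar	WT-4	0.00	0.15	0.00	0.15	485	−17	183	−111
c.1244–4G>A	p.(?)	NCSS	LB	LB	ClinVar	WT-4	0.00	0.08	0.00	0.11	−204	−4	91	−98
c.1269C>T	p.(Tyr423=)	Synonymous	LB	LB	ClinVar	WT-4	0.00	0.11	0.00	0.14	−2497	25	225	−69
c.1298A>G	p.(Tyr433Cys)	Missense	VUS	VUS	ClinVar	WT-4	0.00	0.10	0.01	0.11	−237	54	1	−40
c.1302G>T	p.(Ala434Tyr)	Missense	LB	LB	ClinVar	WT-4	0.00	0.12	0.00	0.12	−233	58	−1596	−36
c.1334A>G	p.(Asp445Gly)	Missense	VUS	LP	ClinVar	WT-4	0.67	0.00	0.93	0.44	90	−4	1	−4
c.1338+3A>T	p.(?)	NCSS	VUS	VUS	ClinVar	WT-4	0.02	0.24	0.01	0.47	599	97	524	3
c.1338+8A>G	p.(?)	NCSS	VUS	VUS	ClinVar	WT-4	0.01	0.10	0.00	0.15	−189	102	197	8
c.1339–3C>G	p.(?)	NCSS	VUS	VUS	LOVD	WT-4	0.79	0.84	0.00	0.34	−1	−3	−538	−114
c.1339–4A>G	p.(?)	NCSS	VUS	VUS	ClinVar	WT-4	0.81	0.12	0.00	0.06	−1	−4	−411	−115
c.1424A>C	p.(His475Pro)	Missense	VUS	VUS	ClinVar	WT-4	0.25	0.08	0.00	0.16	−6	85	−74	−26
c.1450+20T>C	p.(?)	NCSS	LB	LB	ClinVar	WT-4	0.04	0.09	0.01	0.13	40	−1118	−28	20
c.1450+3A>G	p.(?)	NCSS	VUS	VUS	ClinVar	WT-4	0.05	0.27	0.02	0.85	23	−1135	−45	3
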