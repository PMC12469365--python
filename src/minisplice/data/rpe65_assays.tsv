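cDNA Variant	Predicted Protein Variant	ACMG Classification August 2023	ACMG Classification October 2024	Highest SpliceAI Score	Observed Protein Variant	RNA Variant	Percentage of WT Transcript (%)	Percentage of Aberrant Transcript (%)	Identity of Aberrant Transcript(s)
c.643+5G>A	p.(?)	VUS	VUS	0.42	p.Val166Phefs*18	r.[496_725del]	0%	100%	Exon 6 and 7 skipping (83%), exon 6 skipping (8%), exon 7 skipping (3%), and unidentified transcript (6%)
c.644–5T>A	p.(?)	VUS	VUS	0.42	p.Asp215Valfs*4	r.[644_725del]	0%	100%	Exon 7 skipping
c.650A>T	p.(Glu217Val)	VUS	VUS	0.40	p.Asp215Valfs*4	r.[644_725del]	0%	100%	Exon 7 skipping
c.999–3C>G	p.(?)	VUS	VUS	0.76	p.[Phe334Leufs*7,Asp215Valfs*4]	r.[999_1128del,644_725del_999_1128del]	0%	100%	Exon 10 skipping (54%) and exon 7 + 10 skipping (46%)
c.1334A>G	p.(Asp445Gly)	VUS	LP	0.93	p.Asp445Alafs*3	r.[1333_1338del]	0%	100%	5 basepair 3′ truncation of exon 12 (87%) (13% is a PE identified as artefact)
c.1338+3A>T	p.(?)	VUS	VUS	0.47	p.Phe416Leufs*2	r.[1244_1338del]	0%	100%	Exon 12 skipping (3% artefact)
c.1339–3C>G	p.(?)	VUS	VUS	0.84	p.[Leu447Serfs*5,Phe416_Asp483del]	r.[1338_1339ins1339-2_1339-1,1244_1450del]	0%	100%	2 basepair 5′ elongation of exon 13 (34%), exon 12 + 13 skipping (41%), and exon 12 skipping (21%) (4% artefact)
c.713C>G	p.(Ser238Cys)	VUS	VUS	0.25	p.[Asp215Valfs*4,=]	r.[644_725del,=]	7%	93%	Exon 7 skipping (92%) and exon 7 + 10 skipping (1%)
c.726–3C>A	p.(?)	VUS	VUS	0.81	p.[Asp215Glyfs*7,=]	r.[644_858del,=]	9%	91%	Exon 7 and 8 skipping (88%) and intron 7 retention (3%)
c.1244–17T>A	p.(?)	LB	LB	0.15	p.[Phe416Leufs*2,=]	r.[1244_1338del,=]	11%	89%	Exon 12 skipping (87%) (1% artefact)
c.708G>A	p.(Lys236=)	LB	VUS	0.22	p.[Asp215Valfs*,=]	r.[644_725del,=]	12%	88%	Exon 7 skipping (87%) and exon 7 + 10 skipping (1%)
c.294C>A	p.(Ile98=)	VUS	VUS	0.46	p.[Phe83_Arg118delinsLeu,=]	r.[246_353del,=]	13%	87%	Exon 4 skipping (83%) and exon 4 + 5 skipping (4%)
c.676G>T	p.(Val226Phe)	VUS	VUS	0.29	p.[Asp215Valfs*4,=]	r.[644_725del,=]	13%	87%	Exon 7 skipping (86%) and exon 7 + 10 skipping (1%)
c.675C>T	p.(Ile225=)	VUS	VUS	0.27	p.[Asp215Valfs*4,=]	r.[644_725del,=]	14%	86%	Exon 7 skipping (85%) and exon 7 + 10 skipping (1%)
c.676G>A	p.(Val226Ile)	VUS	VUS	0.25	p.[Asp215Valfs*4,=]	r.[644_725del,=]	14%	86%	Exon 7 skipping (85%) and exon 7 + 10 skipping (1%)
c.717C>T	p.(Tyr239=)	LB	LB	0.18	p.[Asp215Valfs*4,=]	r.[644_725del,=]	15%	85%	Exon 7 skipping (80%) and exon 7 + 10 skipping (5%)
c.1092A>G	p.(Glu364=)	VUS	VUS	0.41	p.[Phe334Leufs*7,Asp215Valfs*4,=]	r.[999_1128del,644_725del_999_1128del,=]	16%	84%	Exon 10 skipping (38%), exon 7 + 10 skipping (43%), and exon 7 skipping (4%).
c.701G>A	p.(Arg234Gln)	VUS	VUS	0.21	p.[Asp215Valfs*4,Arg234Gln]	r.[644_725del,=]	19%	81%	Exon 7 skipping (76%), exon 7 + 10 skipping (5%), and an unidentified transcript (3%).
c.718G>T	p.(Val240Phe)	VUS	LP	0.14	p.[Asp215Valfs*4,Val240Phe]	r.[644_725del,=]	20%	80%	Exon 7 skipping (75%) and exon 7 + 10 skipping (5%)
c.1034A>G	p.(Asn345Ser)	VUS	VUS	0.14	p.[Asp215Valfs*4,Asn345Ser,Phe334Leufs*7]	r.[644_725del,=,644_725del_999_1128del,999_1128del]	23%	77%	Exon 7 skipping (43%), exon 10 skipping (16%), and exon 7 + 10 skipping (19%)
c.722A>G	p.(His241Arg)	VUS	LP	0.12	p.[Asp215Valfs*4,His241Arg]	r.[644_725del,=]	23%	77%	Exon 7 skipping (68%) and exon 7 + 10 skipping (9%)
c.1058T>G	p.(Val353Gly)	VUS	VUS	0.28	p.[Asp215Valfs*4,Val353Gly,Phe334Leufs*7]	r.[644_725del_999_1128del,644_725del,=,999_1128del]	24%	76%	Exon 7 skipping (22%), exon 10 skipping (15%), and exon 7 + 10 skipping (39%)
c.725+9A>G	p.(?)	LB	LB	0.12	p.[Asp215Valfs*4,=]	r.[644_725del,=]	26%	74%	Exon 7 skipping (65%) and exon 7 + 10 skipping (9%)
c.1302G>T	p.(Ala434Tyr)	LB	LB	0.12	p.[Phe416Leufs*2,=]	r.[1244_1338del,=]	26%	74%	Exon 12 skipping (73%) (1% artefact)
c.1125C>T	p.(Asp375=)	LB	LB	0.11	p.[Asp215Valfs*4,=,Phe334Leufs*7]	r.[644_725del,644_725del_999_1128del,=,999_1128del]	27%	73%	Exon 7 skipping (42%), exon 10 skipping (16%), and exon 7 + 10 skipping (15%)
c.354G>T	p.(Arg118Ser)	VUS	LP	0.73	p.[Arg118Ser,Phe119Leufs*6,Phe119Leufs*42]	r.[=,354_495del,353_354ins353+1_354-1]	28%	72%	Exon 5 skipping (37%), intron 4 retention (14%), exon 4 + 5 skipping (8%), and two unidentified transcripts (8% and 6%, resp.)
c.1031C>T	p.(Ala344Val)	VUS	VUS	0.12	p.[Asp215Valfs*4,Ala344Val]	r.[644_725del,=]	30%	70%	Exon 7 skipping (45%), exon 10 skipping (12%), and exon 7 + 10 skipping (13%)
c.1118A>G	p.(Asn373Ser)	VUS	VUS	0.18	p.[Asp215Valfs*4,Asn373Ser,Phe334Leufs*7]	r.[644_725del,644_725del_999_1128del,=,999_1128del]	32%	68%	Exon 7 skipping (35%), exon 10 skipping (16%), and exon 7 + 10 skipping (17%)
c.1020C>T	p.(Tyr340=)	LB	LB	0.15	p.[Asp215Valfs*4,=]	r.[644_725del,=]	33%	67%	Exon 7 skipping (50%), exon 10 skipping (10%), and exon 7 + 10 skipping (7%)
c.644–9T>G	p.(?)	VUS	VUS	0.18	p.[Asp215Valfs*4,=]	r.[644_725del,=]	36%	64%	Exon 7 skipping (62%) and exon 7 + 10 skipping (2%)
c.675C>G	p.(Ile225Met)	LB	B	0.17	p.[Asp215Valfs*4,Ile225Met]	r.[644_725del,=]	40%	60%	Exon 7 skipping (58%) and exon 7 + 10 skipping (2%)
c.858+4A>G	p.(?)	VUS	VUS	0.43	p.[=,Asp215Valfs*4]	r.[=,644_725del]	40%	60%	Exon 7 skipping (48%) and exon 7 + 8 skipping (12%)
c.1450+3A>G	p.(?)	VUS	VUS	0.85	p.[=,Val485_Ser533delinsAspGluSerAsnCysCysVal,Phe416_Asp483del]	r.[=,1450_1451ins1450+1_1450+48,1244_1450del]	49%	51%	Exon 13 elongation until 1450 + 48 (15%) and exon 12 + 13 skipping (37%)
c.1338+8A>G	p.(?)	VUS	VUS	0.15	p.[=,Phe416Leufs*2]	r.[=,1244_1338del]	55%	45%	Exon 12 skipping (44%) (1% artefact)
c.260A>G	p.(Asp87Gly)	VUS	LP	0.12	p.[Asp87Gly,Phe83_Arg118delinsLeu]	r.[=, 246_353del]	67%	33%	Exon 4 skipping (33%)
c.294C>T	p.(Ile98=)	VUS	VUS	0.27	p.[=,Phe83_Arg118delinsLeu]	r.[=,246_353del]	71%	29%	Exon 4 skipping (27%) and exon 4 + 5 skipping (2%)
c.292A>G	p.(Ile98Val)	VUS	VUS	0.27	p.[Ile98Val,Phe83_Arg118delinsLeu]	r.[=,246_353del]	75%	25%	Exon 4 skipping (25%)
c.447C>A	p.(Thr149=)	LB	LB	0.14	p.(=)	r.=	81%	19%	Exon 5 skipping (15%) and exon 4 + 5 skipping (4%).
c.447C>T	p.(Thr149=)	LB	LB	0.24	p.(=)	r.=	81%	19%	Exon 5 skipping (14%) and of exon 4 + 5 skipping (6%).
c.417G>A	p.(Val139=)	VUS	VUS	0.20	p.(=)	r.=	82%	18%	Exon 5 skipping (10%), exon 4 + 5 skipping (1%), and one unidentified transcript (6%)
c.297C>T	p.(Val99=)	LB	LB	0.23	p.(=)	r.=	88%	12%	Exon 4 skipping (11%) and exon 4 + 5 skipping (1%)
c.450C>T	p.(Asn150=)	LB	LB	0.15	p.(=)	r.=	91%	9%	Exon 5 skipping (8%) and exon 4 + 5 skipping (1%)
c.425A>G	p.(Asp142Gly)	VUS	VUS	0.21	p.[Asp142Gly]	r.=	94%	6%	Exon 5 skipping (6%).
c.612C>T	p.(Tyr204=)	LB	LB	0.12	p.(=)	r.=	97%	3%	Exon 3 + 4 + 5 skipping (3%)
c.252C>A	p.(Ile84=)	VUS	VUS	0.25	p.(=)	r.=	100%	0%	
c.254G>A	p.(Arg85His)	VUS	LP	0.13	p.(Arg85His)	r.=	100%	0%	
c.267C>T	p.(Tyr89=)	LB	LB	0.15	p.(=)	r.=	100%	0%	
c.291G>A	p.(Arg97=)	LB	LB	0.11	p.(=)	r.=	100%	0%	
c.304G>A	p.(Glu102Lys)	VUS	LP	0.23	p.(Glu102Lys)	r.=	100%	0%	
c.353+4A>T	p.(?)	VUS	VUS	0.26	p.(=)	r.=	100%	0%	
c.371G>A	p.(Arg124Gln)	VUS	VUS	0.13	p.(Arg124Gln)	r.=	100%	0%	
c.375A>G	p.(Gly125=)	VUS	VUS	0.24	p.(=)	r.=	100%	0%	
c.408C>T	p.(Val136=)	LB	LB	0.13	p.(=)	r.=	100%	0%	
c.425A>T	p.(Asp142Val)	VUS	VUS	0.15	p.(Asp142Val)	r.=	100%	0%	
c.576T>A	p.(Ile192=)	VUS	LB	0.15	p.(=)	r.=	100%	0%	
c.1298A>G	p.(Tyr433Cys)	VUS	VUS	0.11	p.(Tyr433Cys)	r.=	100%	0%	
c.1339–4A>G	p.(?)	VUS	VUS	0.81	p.(=)	r.=	100%	0%	
c.1424A>C	p.(His475Pro)	VUS	VUS	0.25	p.(His475Pro)	r.=	100%	0%	
c.1450+20T>C	p.(?)	LB	LB	0.13	p.(=)	r.=	100%	0%	
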