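gene	rsid	chrom	pos	transcript	effect	reference
BLK	rs2736340	8	11343973	NM_001715.3	5' UTR variant	Castillo-Martinez 2016
APOH	.	17	64210757	NM_000042.3	Missense variant (p.Val247Leu)	Lee 2020; Chamorro 2012
F2	rs1799963	11	46761055	NM_000506.5	3' UTR variant	Chen 2015
F5	rs6025	1	169519049	NM_000130.5	Missense variant (p.Gln534Arg)	Chen 2015; Ames 2011
ITGA2	rs1126643	5	52347369	NM_002203.4	Synonymous variant (p.Phe253=)	Jimenez 2008; Islam 2017
ITGB3	rs5918	17	45360730	NM_000212.3	Missense variant (p.Leu59Pro)	Jimenez 2008; Islam 2017
GP1BA	rs2243093	17	4835895	NM_000173.7	5' UTR variant	Islam 2017
IRF5	rs2070197	7	128589000	NM_001098629.3	3' UTR variant	Castillo-Martinez 2016; Xiao 2016
IRF5	rs10954213	7	128589427	NM_001098629.3	3' UTR variant	Castillo-Martinez 2016
PROCR	.	20	.	NM_006404.5	H1 haplotype	Plasin-Rodriguez 2018
PTPN22	rs2476601	1	114377568	NM_015967.7	Missense variant (p.Arg620Trp)	Tang 2012; Dieude 2011
SELP	rs6127	1	169566313	NM_003005.4	Missense variant (p.Asp603Asn)	Islam 2017
SERPINE1	.	7	101126426	NM_000602.3	c.-817dupG	Islam 2017
STAT4	rs7574865	2	191964633	NM_00124385.2	Intronic	Fredi 2015; Yin 2009
STAT4	rs3821236	2	191902758	NM_00124385.2	Intronic	Fredi 2015
STAT4	rs3024866	2	191922841	NM_00124385.2	Intronic	Fredi 2015
TFPI	.	2	188385299	NM_006287.6	Intronic (intron 7 -33T>C)	Islam 2017
TLR4	rs4986790	9	12047502	NM_138554.5	Missense variant (p.Asp299Gly)	Xie 2013; Islam 2017
TNF	rs361525	6	31543101	NM_000594.4	Upstream transcript variant	Islam 2017
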