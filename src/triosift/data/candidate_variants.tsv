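gene	full_name	rsid	chrom	pos	ref	alt	transcript	protein_change	allele_source
ADCY3	Adenylate cyclase 3	rs754839662	2	25050928	C	T	NM_004036.3	p.Val759Met	printed_pair
ATP2B2	ATPase plasma membrane Ca2+ transporting 2	rs751257556	3	10382352	G	A	NM_001001331.2	p.Ala985Val	printed_pair
BCL3	BCL3 transcription coactivator	rs747655476	19	45262063	C	A	NM_005178.4	p.Thr381Asn	printed_pair
CC2D1A	Coiled-coil and C2 domain containing 1A	.	19	14028928	G	T	NM_017721.4	p.Arg265Leu	c_notation:c.794G>T
CROCC	Ciliary rootlet coiled-coil/Rootletin	rs1444279934	1	17270657	A	T	NM_014675.3	p.Gln624Leu	printed_pair
CRTC3	CREB regulated transcription coactivator 3	.	15	91083301	C	T	NM_022769.4	p.Leu55Phe	c_notation:c.163C>T
FAT2	FAT atypical cadherin 2	rs761199516	5	150945648	C	A	NM_001447.2	p.Ala949Ser	printed_pair
GRM7	Glutamate metabotropic receptor 7	rs1480175679	3	7494339	A	C	NM_181874.2	p.Lys407Thr	printed_pair
HSPG2	Heparan sulfate proteoglycan 2	rs766963773	1	22207015	C	T	NM_005529.5	p.Arg679His	printed_pair
IFNA17	Interferon alpha 17	.	9	21227835	A	T	NM_021268.2	p.Tyr113Phe	c_notation:c.338A>T
IMPA2	Inositol monophosphatase 2	rs1423846345	18	12009980	T	C	NM_014214.2	p.Val110Ala	printed_pair
KIF14	Kinesin family member 14	rs373895990	1	200573037	C	T	NM_014875.2	p.Arg598Gln	printed_pair
LTBP2	Latent transforming growth factor beta binding protein 2	rs1310944162	14	74995323	G	A	NM_000428.2	p.Ala744Val	printed_pair
MAP3K10	Mitogen-activated protein kinase kinase kinase 10	.	19	40698296	G	A	NM_002446.3	p.Glu120Lys	c_notation:c.358G>A
MCM8	Minichromosome maintenance 8 homologous recombination repair factor	rs768426546	20	5953350	G	A	NM_001281521.1	p.Arg451His	printed_pair
MRPL48	Mitochondrial ribosomal protein L48	rs745995390	11	73555903	G	T	NM_016055.5	p.Asp85Tyr	printed_pair
MUC16	Mucin 16	rs200972932	19	9067504	C	T	NM_024690.2	p.Glu6648Lys	printed_pair
OR2F1	Olfactory receptor family 2 subfamily F member 1	rs777034277	7	143657370	T	C	NM_012369.2	p.Phe103Leu	printed_pair
OXNAD1	Oxidoreductase NAD binding domain containing 1	rs1456594626	3	16343175	T	G	NM_138381.3	p.Phe159Glu	printed_pair
OXNAD1	Oxidoreductase NAD binding domain containing 1	rs1159857217	3	16343176	T	A	NM_138381.3	p.Phe159Glu	printed_pair
OXNAD1	Oxidoreductase NAD binding domain containing 1	rs1390159575	3	16343177	C	G	NM_138381.3	p.Phe159Glu	printed_pair
PDZD2	PDZ domain containing 2	rs1345334581	5	32098731	C	G	NM_178140.2	p.Pro2737Ala	printed_pair
PLA2G6	Phospholipase A2 group VI	rs780423461	22	38528920	C	G	NM_003560.2	p.Cys332Ser	printed_pair
SRGAP3	SLIT-ROBO Rho GTPase activating protein 3	rs764134718	3	9146464	C	T	NM_014850.3	p.Arg108Gln	printed_pair
USP32	Ubiquitin specific peptidase 32	.	17	58313569	T	C	NM_032582.3	p.Leu390Pro	c_notation:c.1169T>C
ZFAT	Zinc finger and AT-hook domain containing	rs748138009	8	135596174	G	A	NM_020863.3	p.Arg930Cys	printed_pair
ZNF462	Zinc finger protein 462	.	9	109686419	A	T	NM_021224.4	p.Asn76Tyr	c_notation:c.226A>T
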