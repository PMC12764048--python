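gene	protein_change	cdna_change	consequence	clinvar_class	clinvar_variation_id	rsid	literature_reported	allele_count_total
HSD11B2	p.Arg337_Tyr338delinsHis	c.1010_1012del	inframe_indel	P_LP	12097	rs397509434	true	20
HSD11B2	p.Arg359Trp	c.1075C>T	missense	not_reported		rs373865007	true	18
HSD11B2	p.Leu376Pro	c.1127T>C	missense	not_reported		rs762518964	true	18
HSD11B2	p.Asp223Asn	c.667G>A	missense	VUS	12101	rs121917833	true	16
HSD11B2	p.Tyr232_Thr234del	c.695_703del	inframe_indel	LP	3581160	rs765985616	true	16
HSD11B2	p.Ala221Val	c.662C>T	missense	LP	3581156	rs1329450118	true	13
HSD11B2	p.Arg279Cys	c.835C>T	missense	P	12098	rs28934594	true	13
HSD11B2	p.Tyr232Cys	c.695A>G	missense	not_reported			true	10
HSD11B2	p.Arg213Cys	c.637C>T	missense	P	12094	rs28934591	true	8
HSD11B2	p.Ala237Val	c.710C>T	missense	VUS	800834	rs1309642469	true	7
HSD11B2	p.Arg208His	c.623G>A	missense	P_LP	12096	rs28934592	true	7
HSD11B2	p.Ala328Val	c.983C>T	missense	LP	974391	rs1453036708	true	6
HSD11B2	p.Arg337Cys	c.1009C>T	missense	P	12095	rs121917781	true	5
HSD11B2	p.Tyr338His	c.1012T>C	missense	P	31131	rs387907117	true	5
HSD11B2	p.Arg208Cys	c.622C>T	missense	LP	12093	rs121917780	true	4
HSD11B2	p.Gly89Asp	c.266G>A	missense	conflicting	447525	rs1555518481	true	4
HSD11B2	p.Arg374Ter	c.1120C>T	nonsense	not_reported		rs2040980585	true	3
HSD11B2	p.Tyr339Ter	c.1017C>A	nonsense	not_reported		rs2040979207	true	3
HSD11B2	p.Val255GlyfsTer102	c.763dup	frameshift	not_reported		rs1453568208	true	3
HSD11B2	p.Glu115_Leu116del	c.343_348del	inframe_indel	conflicting	12100	rs794726669	true	2
HSD11B2	p.Met243Val	c.727A>G	missense	not_reported			true	2
HSD11B2	p.Phe367del	c.1099_1101del	inframe_indel	not_reported		rs776630118	true	2
HSD11B2	p.Pro227Leu	c.680C>T	missense	P	12099	rs121917782	true	2
HSD11B2	p.Ser26Ter	c.77C>A	nonsense	not_reported			true	2
HSD11B2	p.Leu28ArgfsTer32	c.83_177del	frameshift	P	2033856	rs2040931363	false	2
HSD11B2	p.Arg186Cys	c.556C>T	missense	LP	2137838	rs768507002	true	1
HSD11B2	p.Asp244Asn	c.730G>A	missense	not_reported			true	1
HSD11B2	p.Cys90Arg	c.268T>C	missense	not_reported		rs2040963761	true	1
HSD11B2	p.Leu363Pro	c.1088T>C	missense	not_reported			true	1
HSD11B2	p.Tyr299del	c.895_897del	inframe_indel	VUS	12102	rs794726670	true	1
HSD11B2		c.665-1G>A	splice_site	LP	3581157	rs2040971502	false	1
HSD11B2	p.Ala57GlyfsTer51	c.168_195del	frameshift	P	2876313	rs2040932336	false	1
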