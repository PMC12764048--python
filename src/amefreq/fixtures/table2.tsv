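group	protein_change	cdna_change	consequence	rsid	clinvar_or_literature	allele_count_in_group	cf_per_1e5_printed
afr	p.Leu284Arg	c.851T>G	missense	rs1263624159	false	12	32.0
afr	p.Ala221Val	c.662C>T	missense	rs1329450118	true	3	8.0
afr	p.Gly296Ser	c.886G>A	missense	rs895642778	false	3	8.0
afr	p.Leu28ArgfsTer32	c.83_177del	frameshift	rs2040931363	true	2	5.3
afr	p.Asp317His	c.949G>C	missense	rs147758873	false	2	5.3
amr	p.Asp223Asn	c.667G>A	missense	rs121917833	true	13	43.3
amr	p.Pro381LeufsTer15	c.1142del	frameshift	rs1295704073	false	3	10.0
amr	p.Arg208His	c.623G>A	missense	rs28934592	true	2	6.7
eas	p.Phe107Ile	c.319T>A	missense	rs749262459	false	2	8.9
mid	p.Gly89Asp	c.266G>A	missense	rs1555518481	true	4	132.0
nfe	p.Leu376Pro	c.1127T>C	missense	rs762518964	true	17	2.9
nfe	p.Tyr232_Thr234del	c.695_703del	inframe_indel	rs765985616	true	16	2.7
nfe	p.Arg337_Tyr338delinsHis	c.1010_1012del	inframe_indel	rs397509434	true	16	2.7
nfe	p.Arg279Cys	c.835C>T	missense	rs28934594	true	11	1.9
nfe	p.Tyr232Cys	c.695A>G	missense		true	10	1.7
nfe	p.Arg213Cys	c.637C>T	missense	rs28934591	true	8	1.4
nfe	p.Ala237Val	c.710C>T	missense	rs1309642469	true	5	0.8
nfe	p.Arg337Cys	c.1009C>T	missense	rs121917781	true	5	0.8
nfe	p.Ala328Val	c.983C>T	missense	rs1453036708	true	4	0.7
nfe	p.Tyr338His	c.1012T>C	missense	rs387907117	true	4	0.7
nfe	p.Val255GlyfsTer102	c.763dup	frameshift	rs1453568208	true	3	0.5
nfe	p.Tyr339Ter	c.1017C>A	nonsense	rs2040979207	true	3	0.5
nfe	p.Pro227Leu	c.680C>T	missense	rs121917782	true	2	0.3
nfe	p.Met243Val	c.727A>G	missense		true	2	0.3
nfe	p.Arg374Ter	c.1120C>T	nonsense	rs2040980585	true	2	0.3
sas	p.Tyr353His	c.1057T>C	missense	rs764653595	false	19	41.7
sas	p.Arg359Trp	c.1075C>T	missense	rs373865007	true	8	17.6
sas	p.Phe367Ile	c.1099T>A	missense		false	5	11.0
sas	p.Leu114Ser	c.341T>C	missense	rs770686551	false	4	8.8
sas		c.803_804del	splice_site		false	3	6.6
sas	p.Gln387Ter	c.1159C>T	nonsense		false	2	4.4
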