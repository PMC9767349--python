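individual_id	gene	chrom	pos	ref	alt	transcript	protein_change	consequence	maf	zygosity	alt_reads	total_reads	sample_source	inheritance	cadd
P01	HIF1A	chr14	62187212	G	C	NM_001243084:c.G220C	p.Val74Leu	missense	0.00194	het			blood	maternal	23.0
P02	HIF1A	chr14	62194244	C	T	NM_001243084:c.C716T	p.Pro239Leu	missense	0	het			blood	maternal	25.2
P03	HIF1A	chr14	62204819	G	T	NM_001243084:c.G1336T	p.Asp446Tyr	missense	0.00356	het			blood	maternal	22.1
P04	HIF1A	chr14	62207705	G	A	NM_001243084:c.G1964A	p.Arg655His	missense	4.24e-05	het			blood	paternal	14.22
P05	HIF1A	chr14	62207774	C	T	NM_001243084:c.C2033T	p.Ala678Val	missense	0	het			blood	paternal	21.6
P06	HIF1A	chr14	62207888	C	G	NM_001243084:c.C2147G	p.Ser716Cys	missense	0	het			blood	paternal	1.008
P06	IDH1	chr2	209113112	G	A	NM_005896:c.G395A	p.Arg132His	missense	0	het	20	54	saliva	de_novo	24.9
P07	HIF1A	chr14	62204924	G	A	NM_001243084:c.G1441A	p.Glu481Lys	missense	0	het			blood	unknown	25.0
P07	VHL	chr3	10183605	C	T	NM_000551:c.C74T	p.Pro25Leu	missense	0.00299	het			blood	unknown	16.75
P08	VHL	chr3	10183605	C	T	NM_000551:c.C74T	p.Pro25Leu	missense	0.00299	het			blood	paternal	16.75
P09	VHL	chr3	10183685	G	A	NM_000551:c.G154A	p.Glu52Lys	missense	8.52e-05	het			blood	unknown	14.67
P09	IDH1	chr2	209113112	G	A	NM_005896:c.G395A	p.Arg132His	missense	0	het	15	46	tumor	unknown	24.9
P10	VHL	chr3	10183772	C	T	NM_000551:c.C241T	p.Pro81Ser	missense	0.000218	het			blood	paternal	23.0
P11	VHL	chr3	10191545	A	G	NM_000551:c.A538G	p.Ile180Val	missense	1.06e-05	het			blood	unknown	24.8
P12	VHL	chr3	10191635	C	T	NM_000551:c.C628T	p.Arg210Trp	missense	3.59e-05	het			blood	unknown	15.3
P13	IDH1	chr2	209113112	G	A	NM_005896:c.G395A	p.Arg132His	missense	0	het	30	76	saliva	de_novo	24.9
P14	IDH1	chr2	208243560	A	G	NM_001282386:c.A565G	p.Ile189Val	missense	0.000368	het			blood	maternal	4.69
P15	IDH2	chr15	90627553	C	T	NM_002168:c.C1304T	p.Thr435Met	missense	0.00361	het			blood	paternal	16.01
P16	IDH2	chr15	90627553	C	T	NM_002168:c.C1304T	p.Thr435Met	missense	0.00361	het			blood	maternal+paternal	16.01
P17	IDH2	chr15	90631596	G	A	NM_002168:c.G673A	p.Asp225Asn	missense	0.000287	het			blood	unknown	24.6
P18	KDM4C	chr9	6720959	A	G	NM_001146696:c.A11G	p.Tyr4Cys	missense	1.08e-05	het			blood	paternal	3.376
P18	KDM4C	chr9	7049096	G	A	NM_001146695:c.G2320A	p.Ala774Thr	missense	1.77e-05	het			blood	maternal	26.0
P19	KDM4C	chr9	6981115	G	A	NM_001146695:c.G1112A	p.Arg371Gln	missense	0.00229	het			blood	unknown	3.622
P19	CDKN2A	chr9	21971040	G	A	NM_058195:c.G361A	p.Ala121Thr	missense	0.000225	het			blood	unknown	9.677
P20	CDKN2A	chr9	21971040	G	A	NM_058195:c.G361A	p.Ala121Thr	missense	0.000225	het			blood	maternal	9.677
P21	CDKN2A	chr9	21974777	C	G	NM_000077:c.C50G	p.Ala17Gly	missense	0	het			blood	unknown	12.08
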