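HIF1_ILLUSTRATIVE	small illustrative HIF-1 regulated gene list	ALDOC	ANGPTL4	APLN	BNIP3	CA12	ENO2	GYS1	INHBB	miR210HG	NDRG1	PPP1R3G	STC1	SYNPO	VEGFA	ZNF395	HES1	HSPA2	IPO13	LBH	NR2F2	SMAD7	TGM2
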