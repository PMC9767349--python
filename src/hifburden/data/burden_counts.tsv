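gene	case_carriers	control_carriers	case_noncarriers	control_noncarriers
HIF1A	7	37	87	2017
VHL	6	8	88	2046
IDH1	3	11	91	2043
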