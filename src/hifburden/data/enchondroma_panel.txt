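PTPN11
ACP5
NKX3-2
IDH1
IDH2
PTHR1
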