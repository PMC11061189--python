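STEMNESS_CLASSICAL	classical cancer stem cell markers	ITGA6	CD44	PROM1	NES	MSI1	MYC	NANOG	SOX1	SOX2	POU5F1	VIM	SDC1	SDC2	GPC1	GPC2
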