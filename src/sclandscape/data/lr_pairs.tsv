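ligand	receptor
CXCL13	CXCR5
CXCL9	CXCR3
CXCL10	CXCR3
CCL19	CCR7
CCL21	CCR7
CD40LG	CD40
IL21	IL21R
ICOSLG	ICOS
CD274	PDCD1
TNF	TNFRSF1A
IFNG	IFNGR1
IL2	IL2RA
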