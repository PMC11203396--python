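ligand	receptor	interaction_class	annotation	source_set
CXCL9	CXCR3	activating	T-cell trafficking chemokine	cytokine
CXCL10	CXCR3	activating	T-cell trafficking chemokine	cytokine
CXCL11	CXCR3	activating	T-cell trafficking chemokine	cytokine
CXCL13	CXCR5	activating	B/Tfh-cell recruitment, tertiary lymphoid structures	cytokine
CCL5	CCR5	activating	T/myeloid-cell chemoattraction	cytokine
CCL4	CCR5	activating	T/myeloid-cell chemoattraction	cytokine
IFNG	IFNGR1	activating	interferon-gamma signaling	cytokine
FASLG	FAS	activating	effector-cell cytotoxicity	cytokine
IL2	IL2RB	activating	T-cell proliferation	cytokine
IL15	IL15RA	activating	NK/T-cell homeostasis	cytokine
TNF	TNFRSF1A	activating	proinflammatory signaling	cytokine
IL6	IL6R	activating	inflammatory signaling	cytokine
TGFB1	TGFBR1	inhibitory	immunosuppressive signaling	cytokine
IL10	IL10RA	inhibitory	immunosuppressive signaling	cytokine
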