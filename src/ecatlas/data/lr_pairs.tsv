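pair_id	ligand_components	receptor_components
GAS6_MERTK	GAS6	MERTK
GAS6_AXL	GAS6	AXL
TGFB1_TGFBR1	TGFB1	TGFBR1
PODXL_SELL	PODXL	SELL
CLEC2B_KLRF1	CLEC2B	KLRF1
VEGFA_FLT1	VEGFA	FLT1
VEGFA_KDR	VEGFA	KDR
VEGFA_NRP1	VEGFA	NRP1
SELE_SELPLG	SELE	SELPLG
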