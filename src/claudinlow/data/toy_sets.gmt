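CL_UP	mesenchymal/stemness markers elevated in claudin-low tumors	VIM	SNAI1	SNAI2	TWIST1	TWIST2	ZEB1	ZEB2	CD44	ALDH1A1
CL_DOWN	epithelial junction/differentiation markers lost in claudin-low tumors	CLDN3	CLDN4	CLDN7	CDH1	OCLN	CD24	EPCAM	MUC1
CL_ALL	full 17-gene claudin-low marker signature	CLDN3	CLDN4	CLDN7	CDH1	OCLN	VIM	SNAI1	SNAI2	TWIST1	TWIST2	ZEB1	ZEB2	CD44	CD24	EPCAM	MUC1	ALDH1A1
EMT_TF	EMT-inducing transcription factors	SNAI1	SNAI2	TWIST1	TWIST2	ZEB1	ZEB2
TIGHT_JUNCTION	tight/adherens junction components	CLDN3	CLDN4	CLDN7	OCLN	CDH1
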