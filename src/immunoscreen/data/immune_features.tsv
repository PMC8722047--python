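feature	category	polarity	genes
CD8_T_cells	immune_cell	anti_tumor	CD8A,CD8B,GZMB,GZMK
NK_cells	immune_cell	anti_tumor	KLRD1,NKG7,NCR1,KLRK1
Th1_cells	immune_cell	anti_tumor	TBX21,IFNG,IL12RB2
B_cells	immune_cell	anti_tumor	CD19,MS4A1,CD79A
Dendritic_cells	immune_cell	anti_tumor	CLEC9A,BATF3,XCR1
M2_macrophages	immune_cell	pro_tumor	MRC1,CD163,MSR1
Tregs	immune_cell	pro_tumor	FOXP3,IL2RA,IKZF2
MDSC	immune_cell	pro_tumor	ARG1,NOS2,S100A8
PD_L1	checkpoint_gene	pro_tumor	CD274
CTLA4	checkpoint_gene	pro_tumor	CTLA4
LAG3	checkpoint_gene	pro_tumor	LAG3
ICOS	checkpoint_gene	anti_tumor	ICOS
IFNG_cytokine	cytokine	anti_tumor	IFNG
TNF_cytokine	cytokine	anti_tumor	TNF
IL10_cytokine	cytokine	pro_tumor	IL10
TGFB_cytokine	cytokine	pro_tumor	TGFB1
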