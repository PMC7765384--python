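panel_name	gene_symbol
thrombophilia	F5
thrombophilia	F2
thrombophilia	MTHFR
thrombophilia	F13A1
thrombophilia	PROC
thrombophilia	PROS1
thrombophilia	FGB
thrombophilia	SERPINE1
thrombotic_paps	PF4V1
thrombotic_paps	SELP
thrombotic_paps	TLR2
thrombotic_paps	TLR4
thrombotic_paps	SERPINE1
thrombotic_paps	B2GP1
thrombotic_paps	GP Ia
thrombotic_paps	GP1BA
thrombotic_paps	F2R
thrombotic_paps	F2RL1
thrombotic_paps	F2
thrombotic_paps	TFPI
thrombotic_paps	F3
thrombotic_paps	VEGFA
thrombotic_paps	FLT1
thrombotic_paps	TNF
genes_of_interest	PLA2G6
genes_of_interest	HSPG2
genes_of_interest	BCL3
genes_of_interest	ZFAT
genes_of_interest	ATP2B2
genes_of_interest	CRTC3
genes_of_interest	ADCY3
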