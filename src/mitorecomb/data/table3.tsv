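species	repeat	mode	conformation	path_label	count
C_carlesii	LR9	standard	A	contig7-LR9-contig4	11
C_carlesii	LR9	standard	A	contig2-LR9-contig8	4
C_carlesii	LR9	standard	B	contig2-LR9-contig4	4
C_carlesii	LR9	standard	B	contig7-LR9-contig8	7
C_carlesii	LR10	standard	A	contig6-LR10-contig3	19
C_carlesii	LR10	standard	A	contig2-LR10-contig7	12
C_carlesii	LR10	standard	B	contig6-LR10-contig7	12
C_carlesii	LR10	standard	B	contig2-LR10-contig3	12
C_carlesii	LR11	standard	A	contig5-LR11-contig1	29
C_carlesii	LR11	standard	A	contig12-LR11-contig8	41
C_carlesii	LR11	standard	B	contig5-LR11-contig8	30
C_carlesii	LR11	standard	B	contig12-LR11-contig1	24
Ca_henryi	LR7	standard	A	contig1(ndh3)-LR7-contig5(ATG)	224
Ca_henryi	LR7	standard	A	contig5(CGG)-LR7-contig1(ndh9)	264
Ca_henryi	LR7	standard	B	contig1(ndh3)-LR7-contig5(CCG)	172
Ca_henryi	LR7	standard	B	contig5(CAT)-LR7-contig1(ndh9)	208
Ca_henryi	LR8	standard	A	contig4-LR8-contig3	80
Ca_henryi	LR8	standard	A	contig3-LR8-contig2	96
Ca_henryi	LR8	standard	B	contig4-LR8-contig2	487
Ca_henryi	LR8	standard	B	contig3-LR8-contig3	126
Ca_henryi	LR9	multicopy	A	contig2-LR9-contig6(TAA-TCC)-LR9-contig4	271
Ca_henryi	LR9	multicopy	B	contig2-LR9-contig6(GGA-TTA)-LR9-contig4	42
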