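stage	clin_class	branch	n_variants	n_genes
calling	ALL		125686	25664
stage1	ALL		22626	14754
stage2	UNKNOWN		20541	14043
stage2	CLASS_3		752	849
stage2	CLASS_3PLUS		41	37
stage2	CLASS_45		68	91
stage2	CLASS_12		897	1013
stage2	CLASS_2PLUS		340	378
stage3	UNKNOWN	3.0	14467	11222
stage3	CLASS_3	3.0	309	382
stage3	CLASS_3PLUS	3.0	16	5
stage3	UNKNOWN	3.1	81	78
stage3	CLASS_3	3.1	24	24
stage3	CLASS_3PLUS	3.1	22	21
stage3	UNKNOWN	3.2.1	90	85
stage3	CLASS_3	3.2.1	0
stage3	CLASS_3PLUS	3.2.1	1	1
stage3	UNKNOWN	3.2.2	58	43
stage3	CLASS_3	3.2.2	2	2
stage3	CLASS_3PLUS	3.2.2	0
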