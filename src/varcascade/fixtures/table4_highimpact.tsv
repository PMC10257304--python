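gene	transcript	cancer_link	hgvs_c	hgvs_p	existing_variation	vcv	acmg_class	sample_id	family_id
BRCA2	NM_000059.4	BrC	c.2808_2811del	p.Ala938Profs*21	rs80359351	VCV000009322.91	Class 5	S.03	F.7
BRCA2	NM_000059.4	BrC	c.2808_2811del	p.Ala938Profs*21	rs80359351	VCV000009322.91	Class 5	S.04	F.7
BRCA2	NM_000059.4	BrC	c.7977-1G>C	p.?	rs81002874	VCV000038132.28	Class 5	S.21
MLH1	NM_000249.4	CRC	c.514G>A	p.Glu172Lys	COSV51617106		Class 3	S.23	F.5
MLH1	NM_000249.4	CRC	c.514G>A	p.Glu172Lys	COSV51617106		Class 3	S.25	F.5
MSH2	NM_000251.3	CRC	c.2228C>G	p.Ser743*	rs63751155	VCV000090933.13	Class 5	S.39
MSH6	NM_000179.3	CRC	c.3724_3726del	p.Arg1242del	rs63749942	VCV000089450.22	Class 4	S.30
PMS2	NM_000535.7	CRC	c.614A>C	p.Gln205Pro	rs587779342	VCV000091361.24	Class 4	S.19
PMS2	NM_000535.7	CRC	c.614A>C	p.Gln205Pro	rs587779342	VCV000091361.24	Class 4	S.36	F.2
PMS2	NM_000535.7	CRC	c.1A>G	p.Met1Val	rs587779333	VCV000091323.36	Class 5	S.19
PMS2	NM_000535.7	CRC	c.1A>G	p.Met1Val	rs587779333	VCV000091323.36	Class 5	S.36	F.2
PTCH1	NM_000264.5	GS	c.104G>A	p.Arg35Gln	rs587778627	VCV000135094.9	Class 3	S.44	F.6
SDHA	NM_004168.4	PG	c.762_770+17del	p.Ala255_Gly257del	rs1041809852	VCV000412346.10	Class 3	S.25	F.5
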