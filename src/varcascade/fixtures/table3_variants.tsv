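sample_id	family_id	gene	transcript	hgvs_c	hgvs_p	existing_variation	clinvar	n_samples
S.02	F.8	DNMT3A	NM_022552.5	c.2210T>C	p.Leu737Pro		NR	1
S.03	F.7	BRCA2	NM_000059.4	c.2808_2811del	p.Ala938Profs*21	rs80359351	P	2
S.03	F.7	TYRO3	NM_006293.3	c.1660+1G>C	p.?	rs757748573	NR	3
S.03	F.7	PKD1	NM_001009944.3	c.6605C>T	p.Ala2202Val	rs764264106	VUS	1
S.03	F.7	RBBP8	NM_002894.3	c.298C>T	p.Arg100Trp	rs373804633	P	1
S.04	F.7	BRCA2	NM_000059.4	c.2808_2811del	p.Ala938Profs*21	rs80359351	P	2
S.04	F.7	TYK2	NM_003331.5	c.1011+2T>G	p.?	rs1463636749	NR	1
S.04	F.7	PABPC1	NM_002568.4	c.739-1G>A	p.?	rs759516741	NR	7
S.08		CFTR	NM_000492.4	c.1392G>T	p.Lys464Asn	rs397508198	P	5
S.09		MME	NM_007289.4	c.467del	p.Pro156Leufs*14	rs749320057	P	1
S.09		CACNA1D	NM_001128840.3	c.1750G>A	p.Val584Ile	rs773365038	VUS	1
S.11		FOXP1	NM_001349338.3	c.179A>G	p.Gln60Arg	rs374060287	LP	1
S.13	F.1	MERTK	NM_006343.3	c.1450G>A	p.Gly484Ser	rs527236084	VUS	1
S.13	F.1	PABPC1	NM_002568.4	c.739-1G>A	p.?	rs759516741	NR	7
S.14		RND3	NM_005168.5	c.349-2A>T	p.?	rs1222374113	NR	1
S.15		COL1A1	NM_000088.4	c.4066C>A	p.Arg1356Ser	rs1341595487	VUS	1
S.15		PABPC1	NM_002568.4	c.739-1G>A	p.?	rs759516741	NR	7
S.15		PABPC1	NM_002568.4	c.388-1G>A	p.?	rs771446357	NR	1
S.16		EPHA2	NM_004431.5	c.2162G>A	p.Arg721Gln	rs116506614	CI	1
S.16		CFTR	NM_000492.4	c.1392G>T	p.Lys464Asn	rs397508198	P	5
S.16		PABPC1	NM_002568.4	c.739-1G>A	p.?	rs759516741	NR	7
S.17		UPF1	NM_002911.4	c.2474G>T	p.Ser825Ile		NR	1
S.17		SOX10	NM_006941.4	c.718A>C	p.Thr240Pro	rs1332625359	VUS	1
S.19		TYRO3	NM_006293.3	c.1660+1G>C	p.?	rs757748573	NR	3
S.19		PMS2	NM_000535.7	c.614A>C	p.Gln205Pro	rs587779342	CI	2
S.19		PMS2	NM_000535.7	c.1A>G	p.Met1Val	rs587779333	P/LP	2
S.19		PABPC1	NM_002568.4	c.739-1G>A	p.?	rs759516741	NR	7
S.20		POLG	NM_002693.3	c.2209G>C	p.Gly737Arg	rs121918054	P/LP	1
S.20		DNMT3A	NM_022552.5	c.1122+2T>G	p.?	COSV53057339	NR	1
S.21		BRCA2	NM_000059.4	c.7977-1G>C	p.?	rs81002874	P	1
S.21		PANX2	NM_052839.4	c.1479dup	p.Gly494Argfs*13		NR	1
S.23	F.5	ERCC2	NM_000400.4	c.1480-1G>C	p.?	rs375284572	NR	1
S.23	F.5	MLH1	NM_000249.4	c.514G>A	p.Glu172Lys	COSV51617106	NR	2
S.24		FANCD2	NM_033084.5	c.1588C>T	p.Arg530*	rs962867926	NR	1
S.24		WNT7A	NM_004625.4	c.874C>T	p.Arg292Cys	rs104893835	P	1
S.24		SLC34A2	NM_006424.3	c.1267G>A	p.Gly423Arg	rs769110830	NR	1
S.25	F.5	MLH1	NM_000249.4	c.514G>A	p.Glu172Lys	COSV51617106	NR	2
S.25	F.5	SDHA	NM_004168.4	c.762_770+17del	p.Ala255_Gly257del	rs1041809852	P	1
S.27		CFTR	NM_000492.4	c.2723C>A	p.Thr908Asn	rs369521395	P	1
S.27		PABPC1	NM_002568.4	c.739-1G>A	p.?	rs759516741	NR	7
S.29		PABPC1	NM_002568.4	c.739-1G>A	p.?	rs759516741	NR	7
S.30		GUCY2C	NM_004963.4	c.612-1G>A	p.?	rs763904634	NR	1
S.30		TYRO3	NM_006293.3	c.308+1G>C	p.?	rs764446020	NR	1
S.30		MSH6	NM_000179.3	c.3724_3726del	p.Arg1242del	rs63749942	P/LP	1
S.30		CFTR	NM_000492.4	c.1392G>T	p.Lys464Asn	rs397508198	P	5
S.30		CD36	NM_001001548.3	c.1202_1205del	p.Val401Glufs*4	rs769354931	CI	1
S.31		NOD1	NM_006092.4	c.689T>G	p.Phe230Cys	CM1612670	NR	1
S.32		BRD3	NM_007371.4	c.71dup	p.Glu25Glyfs*51	rs768970491	NR	1
S.33		PABPC1	NM_002568.4	c.367G>T	p.Gly123Cys	rs755674364	NR	1
S.34	F.2	ZBTB7C	NM_001371290.1	c.402_403insC	p.Glu135Argfs*4		NR	1
S.34	F.2	CFTR	NM_000492.4	c.1392G>T	p.Lys464Asn	rs397508198	P	5
S.36	F.2	SYNM	NM_145728.3	c.2523del	p.His842Thrfs*47	COSV60376961	NR	1
S.36	F.2	PMS2	NM_000535.7	c.614A>C	p.Gln205Pro	rs587779342	CI	2
S.36	F.2	PMS2	NM_000535.7	c.1A>G	p.Met1Val	rs587779333	P/LP	2
S.37	F.4	TYRO3	NM_006293.3	c.1660+1G>C	p.?	rs757748573	NR	3
S.38		DDX4	NM_024415.3	c.673+2T>C	p.?	rs201596382	NR	1
S.39		MSH2	NM_000251.3	c.2228C>G	p.Ser743*	rs63751155	P	1
S.43		LRP5	NM_002335.4	c.3562C>T	p.Arg1188Trp	rs141178995	P	1
S.44	F.6	PTCH1	NM_000264.5	c.104G>A	p.Arg35Gln	rs587778627	VUS	1
S.47	F.3	CFTR	NM_000492.4	c.1392G>T	p.Lys464Asn	rs397508198	P	5
S.48	F.3	IL17RD	NM_017563.5	c.392A>C	p.Lys131Thr	rs184758350	CI	1
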