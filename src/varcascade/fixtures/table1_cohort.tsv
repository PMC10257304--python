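sample_id	family_id	crc	other_cancers	family_history
S.13	F.1	Y (50)	-	4 CRC, 1 stomach, 1 melanoma
S.46	F.1	Y (46)	Lung (51)
S.34	F.2	Y (48)	-	3 CRC, 2 melanoma, 1 ovarian, 1 leukaemia, 1lung, 1 kidney, 4 breast, 1 uterine
S.36	F.2	N	Uterine (41)
S.47	F.3	Y (34)	Melanoma (32)	5 CRC, 2 melanoma, 3 breast,1 uterine, 2 kidney, 1 lung, 1 oesophagus, 1 bladder
S.48	F.3	N	Renal (53)
S.37	F.4	Y (38)	-	2 CRC, 1 stomach, 1 throat
S.41	F.4	Y (53)	-
S.23	F.5	Y (51)	-	4 CRC
S.25	F.5	Y (52)	-
S.44	F.6	Y (33)	Uterine (NA)	3 CRC
S.45	F.6	N	Uterine (59)
S.03	F.7	N	Ovarian (78)	1 CRC, 1 ovarian, 2 breast, 1 stomach, 1 renal, 1 liver
S.04	F.7	Y (31)	-
S.01	F.8	Y (64)	-	3 CRC, 1 breast, 1 kidney
S.02	F.8	Y (30 s)	Breast (30 & 70)
S.31		Y (57)	-	9 CRC
S.42		Y (12)	CRC (29)	-
S.19		Y (21)	CRC (40), non-hodgkin lymphoma (42)	-
S.27		N	Ureter (60)	6 CRC
S.18		Y (70)	-	5 CRC, 1 stomach, 1 lung, 1 cervical, 1 polyps
S.43		Y (51)	CRC (64)	5 CRC
S.38		Y (45)	-	5 CRC, 1 acute lymphoblastic leukaemia, 1 hodgkin lymphoma, 1 brain
S.06		Y (60)	Kidney (60), bladder (53)	5 CRC, 1 prostate
S.07		Y (50)	-	5 CRC, 1 uterine
S.24		Y (50)	-	5 CRC, 1 stomach
S.05		Y (64)	-	5 CRC, 1 breast, 1 jaw
S.12		Y (60)	-	4 CRC
S.15		Y (42)	-	4 CRC
S.21		N	Pancreas (62)	4 CRC
S.32		Y (58)	Pancreatic (60)	4 CRC, 3 unknown
S.40		Y (66)	Stomach (NA), kidney (NA)	4 CRC, 4 stomach, 1 brain, 4 eye, 2 lung
S.28		Y (57)	-	4 CRC, 1 kidney
S.17		Y (72)	Kidney (71)	4 CRC
S.08		Y (48)	-	4 CRC, 1 endometrial, 1 throat
S.29		Y (48)	Uterine (56)	3 CRC, 1 abdomen
S.10		Y (53)	Kidney (59)	3 CRC, 2 bladder, 1 lymphoma, 1 brain, 3 melanoma, 1 thyroid, 2 breast, 1 unknown
S.11		Y (60)	Bone (32), breast (57)	3 CRC
S.14		Y (52)	Breast (52)	3 CRC
S.35		Y (36)	Bladder (35), uterine (35)	2 CRC, 4 breast, 2 throat, 2 non-Hodgkin lymphoma
S.30		Y (68)	Ureter (79)	3 CRC, 1 prostate
S.22		Y (54)	CRC (55)	2 CRC, 2 unknown
S.20		Y (55)	Endometrial (41), breast (51)	3 CRC, 3 renal, 1 endometrial, 1 melanoma
S.09		Y (65)	Uterine (50)	2 CRC, 1 breast
S.16		Y (48)	CRC (67)	2 CRC, 1 stomach
S.33		Y (63)	Endometrial (29)	1 CRC, 1 leukaemia, 1 melanoma, 1 endometrial, 3 unknown
S.26		Y (65)	Endometrial (50)	1 Stomach, 1 throat
S.39		Y (77)	Renal (51), uterine (55)	1 CRC, 1 brain, 1 unknown
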