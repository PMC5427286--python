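pos_a	pos_b	peptide_a	peptide_b	d_intra	d_dimer	d_disc	d_between	bands	hybrid	published_class
1	18	MQDQR	ENSIDVVQQGQQKGNQGSSVEK	.	.	.	.	IS	Y	4
1	18	MQDQR	ENSIDVVQQGQQKGNQGSSVEKRPQQR	.	.	.	.	IS	Y	4
1	27	MQDQR	GNQGSSVEKRPQQR	.	.	.	.	IG-M,IS	Y	2
1	106	MQDQR	MRFDMPGLSKEDVK	.	.	.	.	IS	N	1
1	110	MQDQR	EDVKISVEDNVLVIK	.	.	.	.	IG-D	ND	3
1	125	MQDQR	GEQKKEDSDDSWSGR	.	.	.	.	IG-M,IG-D,IS	Y	2
1	126	MQDQR	KEDSDDSWSGR	.	.	.	.	IG-M,IS	Y	2
1	157	MQDQR	IKAELK	.	.	.	.	IG-M,IS	Y	2
1	161	MQDQR	AELKNGVLFITIPK	.	.	.	.	IG-M,IG-D,IS	Y	2
1	173	MQDQR	TKVER	.	.	.	.	IG-M,IS	Y	2
27	121	GNQGSSVEKRPQQR	ISVEDNVLVIKGEQK	.	.	.	.	IS	Y*	4
89	125	APWDIKEEEHEIK	GEQKKEDSDDSWSGR	32.9	20.4	29.0	52.0	IG-M	ND	5
89	126	APWDIKEEEHEIKMR	KEDSDDSWSGR	35.3	18.9	32.6	49.2	IG-M,IS	Y*	5
89	173	APWDIKEEEHEIK	TKVER	11.2	56.4	35.1	32.1	IS	N	1
96	126	APWDIKEEEHEIKMR	KEDSDDSWSGR	28.7	15.9	36.6	46.2	IG-M	ND	5
106	161	FDMPGLSKEDVK	AELKNGVLFITIPK	9.3	16.0	48.3	58.3	IG-M,IS	Y	2
121	126	ISVEDNVLVIKGEQK	KEDSDDSWSGR	17.0	27.0	29.6	35.1	IG-M	N	1
121	173	ISVEDNVLVIKGEQK	TKVER	27.8	45.8	24.0	50.6	IS	Y*	5
125	161	GEQKKEDSDDSWSGR	AELKNGVLFITIPK	17.2	16.1	45.1	52.0	IG-D	ND	3
126	157	KEDSDDSWSGR	IKAELKNGVLFITIPK	26.9	23.5	47.0	46.2	IG-M	ND	5
126	161	KEDSDDSWSGR	AELKNGVLFITIPK	18.4	16.7	48.1	51.4	IG-D,IS	Y*	4
153	157	LQLPDNCEKDK	IKAELK	9.3	44.8	33.6	58.6	IG-M	ND	5
157	173	IKAELK	TKVER	16.7	50.6	26.8	46.2	IG-M,IG-D	ND	5
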