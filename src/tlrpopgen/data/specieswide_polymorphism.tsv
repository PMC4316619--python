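gene	two_n	nsites	cds	n_alleles	S	pi	pi_nonsyn	pi_syn	ni	mk_p	f_lo95	f	f_hi95
TLR01	32	2358	1.00	25	160	0.0146	0.0105	0.0293	0.93	1.000	0.23	0.28	0.35
TLR02	32	2313	0.96	21	87	0.0090	0.0066	0.0174	0.74	0.451	0.23	0.30	0.41
TLR03	32	1776	0.66	26	132	0.0136	0.0074	0.0351	0.46	0.086	0.17	0.22	0.27
TLR05L	32	1782	0.89	24	146	0.0117	0.0068	0.0271	0.28	0.063	0.19	0.25	0.30
TLR07	32	3045	0.97	27	171	0.0109	0.0044	0.0331	0.69	0.348	0.16	0.21	0.25
TLR09A	32	3090	0.99	23	118	0.0080	0.0047	0.0194	0.96	1.000	0.20	0.26	0.34
TLR09B	30	2083	0.67	19	119	0.0121	0.0089	0.0230	0.40	0.075	0.25	0.31	0.40
TLR13	32	2502	0.88	26	181	0.0100	0.0067	0.0209	1.68	0.303	0.22	0.27	0.33
TLR21	32	2841	0.98	26	215	0.0141	0.0077	0.0347	0.99	1.000	0.18	0.23	0.28
TLR22A	32	2787	0.98	23	149	0.0097	0.0054	0.0242	0.95	1.000	0.20	0.25	0.30
TLR22B	32	2026	0.71	26	145	0.0141	0.0084	0.0334	1.12	1.000	0.22	0.28	0.36
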