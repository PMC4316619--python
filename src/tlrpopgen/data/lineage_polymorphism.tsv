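gene	nsites	cds	n_alleles_lm	n_alleles_lvg	S_lm	S_lvg	pi_lm	pi_lvg	pi_syn_lm	pi_syn_lvg	pi_nonsyn_lm	pi_nonsyn_lvg
TLR01	1626	0.69	13	18	65	39	0.0112	0.0047	0.0220	0.0113	0.0081	0.0028
TLR02	1656	0.69	10	12	23	35	0.0024	0.0031	0.0074	0.0047	0.0009	0.0027
TLR03	1620	0.60	17	19	65	47	0.0097	0.0037	0.0289	0.0079	0.0041	0.0025
TLR05L	1463	0.73	5	18	5	41	0.0008	0.0051	0.0019	0.0139	0.0004	0.0024
TLR07	1527	0.49	22	17	44	58	0.0067	0.0065	0.0143	0.0195	0.0045	0.0026
TLR09A	1683	0.54	7	14	27	39	0.0056	0.0048	0.0097	0.0112	0.0034	0.0029
TLR09B	1452	0.47	14	16	15	26	0.0017	0.0046	0.0029	0.0105	0.0013	0.0028
TLR13	1479	0.52	16	14	46	48	0.0092	0.0047	0.0168	0.0067	0.0068	0.0040
TLR21	1611	0.55	25	11	82	15	0.0124	0.0017	0.0283	0.0033	0.0074	0.0015
TLR22A	1723	0.60	9	16	47	47	0.0095	0.0041	0.0221	0.0130	0.0058	0.0015
TLR22B	1387	0.48	18	18	53	43	0.0095	0.0070	0.0219	0.0151	0.0058	0.0047
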