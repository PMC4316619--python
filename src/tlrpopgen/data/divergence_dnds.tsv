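gene	ncodons	cds	dN	dS	dnds
TLR01	786	1.00	0.056	0.142	0.39
TLR02	799	1.00	0.069	0.184	0.37
TLR03	901	1.00	0.057	0.186	0.31
TLR05	888	1.00	0.089	0.170	0.52
TLR05L	664	1.00	0.064	0.162	0.40
TLR07	1041	0.99	0.048	0.211	0.22
TLR08	534	0.50	0.076	0.169	0.45
TLR09A	1038	1.00	0.056	0.154	0.37
TLR09B	1034	1.00	0.079	0.147	0.54
TLR12	0	0.00	NA	NA	NA
TLR13	566	0.59	0.114	0.160	0.71
TLR14	819	1.00	0.050	0.167	0.30
TLR19	955	1.00	0.084	0.204	0.41
TLR21	707	0.73	0.083	0.316	0.26
TLR22A	871	0.91	0.067	0.146	0.46
TLR22B	956	1.00	0.059	0.151	0.39
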