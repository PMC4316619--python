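gene	mk_p_lm	mk_p_lvg	hka_p_lm	hka_p_lvg	D_lm	D_lvg	D_syn_lm	D_syn_lvg	D_nonsyn_lm	D_nonsyn_lvg	H_lm	H_lvg	H_syn_lm	H_syn_lvg	H_nonsyn_lm	H_nonsyn_lvg
TLR01	0.806	0.644	0.273	0.968	0.57	-0.74	0.52	-0.45	0.57	-0.94	0.75	-0.98	-0.11	-2.50	1.05	1.63
TLR02	1.000	0.621	0.108	0.695	-0.93	-1.41	0.50	-1.08	-1.93	-1.45	-6.15	-4.03	-3.25	-1.46	-2.95	-3.72
TLR03	0.264	0.824	0.471	0.752	0.00	-1.79	0.10	-1.77	-0.19	-1.63	4.14	-16.66	3.49	-11.46	0.55	-5.14
TLR05L	0.035	0.170	0.006	0.359	-0.16	-0.94	-0.72	-0.52	1.25	-1.34	0.66	0.19	0.32	-0.55	0.24	0.74
TLR07	0.139	0.741	0.152	0.041	-0.06	-1.07	0.00	-0.99	-0.10	-1.10	2.13	-6.45	0.11	-3.08	1.97	-3.26
TLR09A	0.435	1.000	0.165	0.735	1.38	-0.61	1.39	-0.60	1.18	-0.56	-4.38	2.44	-1.46	0.02	-1.88	1.98
TLR09B	0.112	0.006	0.115	0.305	-1.06	0.15	-0.84	-0.53	-1.01	1.29	0.84	-1.81	-0.20	-1.54	0.76	-0.33
TLR13	0.361	0.576	0.206	0.234	0.85	-1.63	1.04	-1.58	0.63	-1.20	3.20	-11.04	1.01	-5.43	2.19	-5.28
TLR21	0.843	0.452	0.594	0.001	0.01	-0.83	0.12	-0.76	-0.07	-0.74	-5.17	-1.78	-1.21	-0.93	-2.20	1.13
TLR22A	0.818	0.198	0.685	0.743	1.43	-1.45	1.43	-1.01	1.37	-1.92	1.91	-7.97	0.94	-3.30	0.99	-4.04
TLR22B	0.723	1.000	0.140	0.123	0.15	-0.26	0.58	0.25	-0.25	-0.62	-7.10	-0.65	-4.23	2.95	-0.89	0.23
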