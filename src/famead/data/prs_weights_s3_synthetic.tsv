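variant_id	risk_allele	weight	af	imputation_r2	is_apoe_region
prs_snp_01	G	0.063	0.183	0.58	False
prs_snp_02	T	0.112	0.303	0.76	False
prs_snp_03	T	0.084	0.513	0.88	False
prs_snp_04	C	0.076	0.324	0.97	False
prs_snp_05	T	0.112	0.076	0.53	False
prs_snp_06	G	0.123	0.326	0.73	False
prs_snp_07	A	0.207	0.471	0.90	False
prs_snp_08	C	0.161	0.508	0.87	False
prs_snp_09	C	0.174	0.432	0.47	False
prs_snp_10	G	0.076	0.334	0.43	False
prs_snp_11	T	0.205	0.577	0.93	False
prs_snp_12	T	0.229	0.078	0.99	False
prs_snp_13	C	0.175	0.098	0.46	False
prs_snp_14	T	0.109	0.388	0.43	False
prs_snp_15	A	0.210	0.218	0.65	False
prs_snp_16	C	0.153	0.230	0.62	False
prs_snp_17	A	0.085	0.593	0.62	False
prs_snp_18	A	0.109	0.387	0.45	False
prs_snp_19	A	0.069	0.173	0.77	False
prs_snp_20	T	0.225	0.357	0.95	False
prs_snp_21	C	0.215	0.425	0.78	False
prs_snp_22	G	0.100	0.565	0.83	False
prs_snp_23	C	0.222	0.253	0.70	False
prs_snp_24	T	0.147	0.181	0.50	False
prs_snp_25	C	0.226	0.093	0.98	False
prs_snp_26	A	0.245	0.054	0.58	False
prs_snp_27	T	0.065	0.435	0.94	False
prs_snp_28	G	0.082	0.386	0.43	False
prs_snp_29	G	0.249	0.353	0.99	False
prs_snp_30	C	0.079	0.592	0.72	False
prs_snp_31	A	0.109	0.538	0.78	False
prs_snp_32	G	0.225	0.243	0.99	False
prs_snp_33	T	0.078	0.355	0.67	False
prs_snp_34	C	0.157	0.156	0.78	False
prs_snp_35	G	0.148	0.502	0.60	False
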