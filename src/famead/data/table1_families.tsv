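family_id	n_patients	onset_age	pv_gene	vus_gene	apoe_risk	prs	has_e44	flags
1	2	57.0	APP		0.24	-0.49	0	PV
2	2	48.0	GRN		0.24	0.61	0	PV,PRS
3	2	69.5	PSEN1		0.01	-0.26	0	PV
4	2	56.0	PSEN1		-0.36	-0.08	0	PV
5	2	64.5	PSEN1		-0.36	-0.33	0	PV
6	2	49.0	PSEN1		0.84	0.06	0	PV
7	2	59.0	PSEN1		0.24	-0.23	0	PV
8	2	57.5	SORL1		1.44	0.47	1	PV,APOE,PRS
9	2	65.0		ABCA7	2.04	0.20	1	VUS,APOE
10	2	64.0		BIN1	1.44	0.02	1	VUS,APOE
11	2	69.5		CR1	1.44	0.37	1	VUS,APOE
12	2	69.5		FERMT2	2.04	0.20	1	VUS,APOE
13	2	69.0		MADD	2.04	-0.02	1	VUS,APOE
14	2	63.0		PRNP	0.24	0.12	0	VUS
15	2	59.5		SORL1	1.44	0.15	1	VUS,APOE
16	2	73.0		SQSTM1	0.84	0.42	0	VUS
17	2	68.0			1.44	0.60	1	APOE,PRS
18	4	70.3			2.04	0.56	1	APOE,PRS
19	2	62.5			1.44	-0.17	1	APOE
20	2	68.5			1.44	-0.14	1	APOE
21	2	62.0			2.04	0.32	1	APOE
22	2	56.0			2.04	-0.15	1	APOE
23	2	65.0			1.44	-0.04	1	APOE
24	2	68.0			1.44	-0.08	1	APOE
25	3	56.7			1.64	0.41	1	APOE
26	3	59.0			1.24	-0.30	1	APOE
27	2	59.0			2.04	0.01	1	APOE
28	2	67.5			-0.36	-0.18	0	none
29	3	63.5			0.44	-0.33	0	none
30	2	64.9			-0.36	-0.10	0	none
31	2	73.0			0.84	-0.01	0	none
32	2	63.5			-0.36	-0.19	0	none
33	2	63.5			0.84	0.19	0	none
34	2	59.5			0.24	0.04	0	none
35	2	69.0			0.24	-0.15	0	none
36	2	59.0			0.84	0.19	0	none
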