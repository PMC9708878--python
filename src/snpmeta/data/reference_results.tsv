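table	polymorphism	contrast	subgroup	k	or	ci_low	ci_high	i2	p_het	model
t5	tgfb1_509	allele	Overall	17	1.25	1.06	1.48	78	<0.00001	RE
t5	tgfb1_509	homozygote	Overall	17	1.51	1.08	2.11	77	<0.00001	RE
t5	tgfb1_509	heterozygote	Overall	17	1.31	1.09	1.58	49	0.01	RE
t5	tgfb1_509	dominant	Overall	17	1.38	1.10	1.73	69	<0.00001	RE
t5	tgfb1_509	recessive	Overall	17	1.25	1.00	1.57	65	0.0001	RE
t5	tgfb1_codon10	allele	Overall	13	1.12	1.02	1.23	18	0.27	FE
t5	tgfb1_codon10	homozygote	Overall	13	1.28	1.06	1.54	23	0.21	FE
t5	tgfb1_codon10	heterozygote	Overall	13	1.05	0.90	1.23	35	0.1	FE
t5	tgfb1_codon10	dominant	Overall	13	1.11	0.96	1.29	28	0.17	FE
t5	tgfb1_codon10	recessive	Overall	13	1.23	1.05	1.44	29	0.15	FE
t5	tgfb1_codon25	allele	Overall	19	1.09	0.78	1.52	69	<0.00001	RE
t5	tgfb1_codon25	homozygote	Overall	14	0.97	0.38	2.51	55	0.007	RE
t5	tgfb1_codon25	heterozygote	Overall	19	1.01	0.73	1.39	55	0.002	RE
t5	tgfb1_codon25	dominant	Overall	19	1.07	0.76	1.52	64	<0.0001	RE
t5	tgfb1_codon25	recessive	Overall	14	1.00	0.42	2.41	49	0.02	RE
t6	tgfb1_509	allele	HCC	5	1.28	0.90	1.84	88	<0.00001	RE
t6	tgfb1_509	allele	Cirrhosis	3	1.54	1.27	1.86	42	0.18	FE
t6	tgfb1_509	allele	CHB	3	1.04	0.87	1.23	0	0.54	FE
t6	tgfb1_509	allele	CHC	3	1.73	1.38	2.18	0	0.85	FE
t6	tgfb1_509	allele	ALD	2	0.85	0.46	1.57	85	0.009	RE
t6	tgfb1_509	allele	PBC	1	1.13	0.70	1.83	-	-	-
t6	tgfb1_509	homozygote	HCC	5	1.57	0.77	3.21	86	<0.00001	RE
t6	tgfb1_509	homozygote	Cirrhosis	3	2.21	1.52	3.21	35	0.22	FE
t6	tgfb1_509	homozygote	CHB	3	1.07	0.76	1.51	0	0.56	FE
t6	tgfb1_509	homozygote	CHC	3	3.04	1.89	4.88	0	0.72	FE
t6	tgfb1_509	homozygote	ALD	2	0.67	0.17	2.71	86	0.007	RE
t6	tgfb1_509	homozygote	PBC	1	1.19	0.45	3.13	-	-	-
t6	tgfb1_509	heterozygote	HCC	5	1.42	0.89	2.25	77	0.02	RE
t6	tgfb1_509	heterozygote	Cirrhosis	3	1.53	1.12	2.10	26	0.26	FE
t6	tgfb1_509	heterozygote	CHB	3	1.19	0.87	1.63	38	0.2	FE
t6	tgfb1_509	heterozygote	CHC	3	1.70	1.15	2.52	0	0.86	FE
t6	tgfb1_509	heterozygote	ALD	2	0.96	0.68	1.35	20	0.26	FE
t6	tgfb1_509	heterozygote	PBC	1	1.33	0.62	2.82	-	-	-
t6	tgfb1_509	dominant	HCC	5	1.48	0.86	2.53	85	<0.0001	RE
t6	tgfb1_509	dominant	Cirrhosis	3	1.74	1.30	2.33	41	0.18	FE
t6	tgfb1_509	dominant	CHB	3	1.15	0.85	1.54	29	0.24	FE
t6	tgfb1_509	dominant	CHC	3	2.04	1.41	2.95	0	0.98	FE
t6	tgfb1_509	dominant	ALD	2	0.87	0.47	1.61	72	0.06	RE
t6	tgfb1_509	dominant	PBC	1	1.29	0.63	2.61	-	-	-
t6	tgfb1_509	recessive	HCC	5	1.21	0.80	1.83	73	0.005	RE
t6	tgfb1_509	recessive	Cirrhosis	3	1.71	1.24	2.36	0	0.48	FE
t6	tgfb1_509	recessive	CHB	3	0.98	0.75	1.28	0	0.81	FE
t6	tgfb1_509	recessive	CHC	3	2.11	1.44	3.11	0	0.51	FE
t6	tgfb1_509	recessive	ALD	2	0.70	0.21	2.30	84	0.01	RE
t6	tgfb1_509	recessive	PBC	1	1.01	0.42	2.41	-	-	-
t7	tgfb1_codon10	allele	Cirrhosis	3	0.99	0.82	1.20	24	0.27	FE
t7	tgfb1_codon10	allele	CHB	2	1.35	1.05	1.75	0	0.95	FE
t7	tgfb1_codon10	allele	CHC	6	1.12	0.97	1.29	0	0.84	FE
t7	tgfb1_codon10	allele	AIH	1	1.50	1.12	2.01	-	-	-
t7	tgfb1_codon10	allele	ALD	1	0.88	0.65	1.20	-	-	-
t7	tgfb1_codon10	homozygote	Cirrhosis	3	0.97	0.67	1.41	6	0.34	FE
t7	tgfb1_codon10	homozygote	CHB	2	2.33	1.28	4.22	0	0.75	FE
t7	tgfb1_codon10	homozygote	CHC	6	1.28	0.96	1.70	0	0.84	FE
t7	tgfb1_codon10	homozygote	AIH	1	2.15	1.18	3.58	-	-	-
t7	tgfb1_codon10	homozygote	ALD	1	0.79	0.43	1.46	-	-	-
t7	tgfb1_codon10	heterozygote	Cirrhosis	3	1.04	0.76	1.43	35	0.21	FE
t7	tgfb1_codon10	heterozygote	CHB	2	2.58	1.52	4.37	0	0.34	FE
t7	tgfb1_codon10	heterozygote	CHC	6	0.95	0.76	1.20	0	0.82	FE
t7	tgfb1_codon10	heterozygote	AIH	1	0.35	0.11	1.12	-	-	-
t7	tgfb1_codon10	heterozygote	ALD	1	0.92	0.58	1.46	-	-	-
t7	tgfb1_codon10	dominant	Cirrhosis	3	1.02	0.76	1.37	43	0.17	FE
t7	tgfb1_codon10	dominant	CHB	2	2.51	1.50	4.18	0	0.41	FE
t7	tgfb1_codon10	dominant	CHC	6	1.04	0.84	1.30	0	0.92	FE
t7	tgfb1_codon10	dominant	AIH	1	1.18	0.74	1.86	-	-	-
t7	tgfb1_codon10	dominant	ALD	1	0.88	0.58	1.35	-	-	-
t7	tgfb1_codon10	recessive	Cirrhosis	3	0.96	0.69	1.31	0	0.79	FE
t7	tgfb1_codon10	recessive	CHB	2	1.13	0.74	1.71	0	0.56	FE
t7	tgfb1_codon10	recessive	CHC	6	1.32	1.04	1.68	0	0.54	FE
t7	tgfb1_codon10	recessive	AIH	1	2.32	1.46	3.70	-	-	-
t7	tgfb1_codon10	recessive	ALD	1	0.82	0.47	1.45	-	-	-
t8	tgfb1_codon25	allele	HCC	1	0.67	0.30	1.48	-	-	-
t8	tgfb1_codon25	allele	Cirrhosis	2	1.57	0.95	2.59	0	0.42	FE
t8	tgfb1_codon25	allele	CHB	2	1.22	0.80	1.87	0	0.87	FE
t8	tgfb1_codon25	allele	CHC	10	0.91	0.58	1.44	55	0.02	RE
t8	tgfb1_codon25	allele	AIH	2	2.37	0.45	12.35	94	<0.0001	RE
t8	tgfb1_codon25	allele	ALD	2	0.28	0.02	5.29	76	0.04	RE
t8	tgfb1_codon25	homozygote	HCC	1	0.09	0.00	2.17	-	-	-
t8	tgfb1_codon25	homozygote	Cirrhosis	1	2.00	0.15	26.73	-	-	-
t8	tgfb1_codon25	homozygote	CHB	2	1.04	0.28	3.90	38	0.2	FE
t8	tgfb1_codon25	homozygote	CHC	6	0.44	0.17	1.14	0	0.77	FE
t8	tgfb1_codon25	homozygote	AIH	2	14.73	3.92	55.37	0	0.48	FE
t8	tgfb1_codon25	homozygote	ALD	2	0.38	0.09	1.63	7	0.3	FE
t8	tgfb1_codon25	heterozygote	HCC	1	0.69	0.18	2.60	-	-	-
t8	tgfb1_codon25	heterozygote	Cirrhosis	2	2.15	1.13	4.10	0	0.39	FE
t8	tgfb1_codon25	heterozygote	CHB	2	1.29	0.80	2.08	0	0.49	FE
t8	tgfb1_codon25	heterozygote	CHC	10	0.92	0.56	1.51	56	0.01	RE
t8	tgfb1_codon25	heterozygote	AIH	2	0.90	0.23	3.47	81	0.02	RE
t8	tgfb1_codon25	heterozygote	ALD	2	0.33	0.02	4.74	70	0.07	RE
t8	tgfb1_codon25	dominant	HCC	1	0.60	0.16	2.25	-	-	-
t8	tgfb1_codon25	dominant	Cirrhosis	2	2.14	1.12	4.06	0	0.43	FE
t8	tgfb1_codon25	dominant	CHB	2	1.26	0.80	2.00	0	0.78	FE
t8	tgfb1_codon25	dominant	CHC	10	0.90	0.55	1.50	59	0.01	RE
t8	tgfb1_codon25	dominant	AIH	2	1.70	0.32	9.14	92	0.0005	RE
t8	tgfb1_codon25	dominant	ALD	2	0.26	0.01	5.57	77	0.04	RE
t8	tgfb1_codon25	recessive	HCC	1	0.11	0.00	2.35	-	-	-
t8	tgfb1_codon25	recessive	Cirrhosis	1	0.53	0.07	4.08	-	-	-
t8	tgfb1_codon25	recessive	CHB	2	1.01	0.27	3.77	41	0.19	FE
t8	tgfb1_codon25	recessive	CHC	6	0.53	0.20	1.41	0	0.93	FE
t8	tgfb1_codon25	recessive	AIH	2	14.69	3.98	54.23	0	0.58	FE
t8	tgfb1_codon25	recessive	ALD	2	0.51	0.11	2.28	0	0.54	FE
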