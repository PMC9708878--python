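study_id	polymorphism	disease	case_aa	case_ab	case_bb	ctrl_aa	ctrl_ab	ctrl_bb	allele_common	allele_variant	country	ethnicity	nos_score	hwe_case_printed	hwe_ctrl_printed
Armendariz 2008 ALD	codon 25	ALD	7	0	0	11	13	6	Arg	Pro	Mexico	Mixed-race	8	/	0.552
Armendariz 2008 CHC	codon 25	CHC	13	0	0	11	13	6	Arg	Pro	Mexico	Mixed-race	8	/	0.552
Basturk 2008 CHB	codon 25	CHB	23	4	0	51	6	3	Arg	Pro	Turkey	Caucasian	8	0.678	0.001
Dondeti 2017 CHB	codon 25	CHB	96	19	0	104	13	2	Arg	Pro	Egypt	Egyptian	9	0.334	0.054
Fabricio-Silva 2015 CHC	codon 25	CHC	213	30	2	161	26	2	Arg	Pro	Brazil	Mixed-race	8	0.417	0.420
Falleti 2008 Cirrhosis	codon 25	Cirrhosis	156	31	0	127	13	0	Arg	Pro	Italy	Caucasian	9	0.216	0.565
Hosseini Razavi 2014 CHB	codon 25	CHB	193	23	4	197	21	2	Arg	Pro	Iran	Caucasian	8	0.003	0.105
Maria 2013 CHC	codon 25	CHC	34	4	0	46	4	0	Arg	Pro	Mexico	Mixed-race	9	0.732	0.768
Nomair 2021 Cirrhosis	codon 25	Cirrhosis	2	32	2	4	14	2	Arg	Pro	Egypt	Egyptian	8	0.000	0.064
Nomair 2021 HCC	codon 25	HCC	10	24	0	4	14	2	Arg	Pro	Egypt	Egyptian	8	0.001	0.064
Obada 2017 CHC	codon 25	CHC	127	22	1	84	15	1	Arg	Pro	Egypt	Egyptian	9	0.965	0.721
Oliver 2005 ALD	codon 25	ALD	135	28	2	148	34	3	Arg	Pro	Spain	Caucasian	8	0.690	0.523
Paladino 2010 AIH	codon 25	AIH	154	15	9	156	32	1	Arg	Pro	America	NA	6	0.000	0.638
Pereira 2008 CHC	codon 25	CHC	113	14	1	64	29	1	Arg	Pro	Brazil	Mixed-race	9	0.451	0.244
Romani 2011 CHC	codon 25	CHC	145	18	1	151	16	2	Arg	Pro	Iran	Caucasian	7	0.595	0.052
Sanchez-Parada 2013 CHC	codon 25	CHC	34	4	0	46	4	0	Arg	Pro	Mexico	Mixed-race	8	0.732	0.768
Vidigal 2002 CHC	codon 25	CHC	68	11	1	34	3	0	Arg	Pro	America	Caucasian	9	0.480	0.797
Yousefi 2019 AIH	codon 25	AIH	26	7	10	119	17	2	Arg	Pro	Iran	Caucasian	8	0.000	0.146
Zein 2004 CHC Caucasian	codon 25	CHC	25	6	0	33	3	0	Arg	Pro	Mixed	Caucasian	7	0.551	0.794
Zein 2004 CHC Egyptian	codon 25	CHC	21	3	0	41	4	0	Arg	Pro	Mixed	Egyptian	7	0.744	0.755
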