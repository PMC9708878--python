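study_id	polymorphism	disease	case_aa	case_ab	case_bb	ctrl_aa	ctrl_ab	ctrl_bb	allele_common	allele_variant	country	ethnicity	nos_score	hwe_case_printed	hwe_ctrl_printed
Basturk 2008 CHB	codon 10	CHB	2	20	5	16	31	13	Leu	Pro	Turkey	Caucasian	8	0.009	0.781
Dondeti 2017 CHB	codon 10	CHB	44	70	1	40	70	9	Leu	Pro	Egypt	Egyptian	9	0.000	0.004
Eskandari 2017 CHB	codon 10	CHB	23	118	55	46	103	49	Leu	Pro	Iran	Caucasian	8	0.001	0.567
Fabricio-Silva 2015 CHC	codon 10	CHC	70	117	58	54	103	32	Leu	Pro	Brazil	Mixed-race	8	0.505	0.149
Falleti 2008 Cirrhosis	codon 10	Cirrhosis	51	95	42	49	62	29	Leu	Pro	Italy	Caucasian	9	0.859	0.257
Lee 2011 Cirrhosis	codon 10	Cirrhosis	61	79	42	35	53	31	Leu	Pro	Korea	Asian	7	0.099	0.238
Obada 2017 CHC	codon 10	CHC	42	78	30	32	47	21	Leu	Pro	Egypt	Egyptian	9	0.567	0.628
Oliver 2005 ALD	codon 10	ALD	72	68	25	75	77	33	Leu	Pro	Spain	Caucasian	8	0.186	0.096
Paladino 2010 AIH	codon 10	AIH	46	65	67	55	95	39	Leu	Pro	America	NA	6	0.001	0.863
Pereira 2008 CHC	codon 10	CHC	26	65	37	24	49	21	Leu	Pro	Brazil	Mixed-race	9	0.793	0.672
Romani 2011 CHC	codon 10	CHC	50	81	33	49	85	35	Leu	Pro	Iran	Caucasian	7	0.985	0.867
Suzuki 2003 CHC	codon 10	CHC	56	84	66	28	52	21	Leu	Pro	Japan	Asian	8	0.009	0.727
Talaat 2013 CHB	codon 10	CHB	10	44	11	0	15	12	Leu	Pro	Egypt	Egyptian	9	0.004	0.046
Vidigal 2002 CHC	codon 10	CHC	29	38	13	12	21	4	Leu	Pro	America	Caucasian	9	0.926	0.246
Wang 2008 Cirrhosis	codon 10	Cirrhosis	34	53	31	25	50	29	Leu	Pro	China	Asian	9	0.272	0.706
Yousefi 2019 AIH	codon 10	AIH	6	7	31	27	91	20	Leu	Pro	Iran	Caucasian	8	0.000	0.000
Zein 2004 CHC Caucasian	codon 10	CHC	10	4	17	12	3	21	Leu	Pro	Mixed	Caucasian	7	0.000	0.000
Zein 2004 CHC Egyptian	codon 10	CHC	6	3	15	12	11	22	Leu	Pro	Mixed	Egyptian	7	0.001	0.001
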