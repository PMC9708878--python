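study_id	polymorphism	disease	case_aa	case_ab	case_bb	ctrl_aa	ctrl_ab	ctrl_bb	allele_common	allele_variant	country	ethnicity	nos_score	hwe_case_printed	hwe_ctrl_printed
Bader El Din 2017 CHC	-509C/T	CHC	22	32	18	23	23	4	C	T	Egypt	Egyptian	9	0.358	0.595
Brito 2020 CHC	-509C/T	CHC	17	49	31	90	154	56	C	T	Brazil	Mixed-race	7	0.754	0.488
Conde 2013 CHB	-509C/T	CHB	17	19	17	24	39	34	C	T	Brazil	Mixed-race	8	0.039	0.065
Dondeti 2017 CHB	-509C/T	CHB	11	85	19	35	75	9	C	T	Egypt	Egyptian	9	0.000	0.000
Eskandari 2017 CHB	-509C/T	CHB	78	78	22	71	54	29	C	T	Iran	Caucasian	8	0.715	0.003
Falleti 2008 Cirrhosis	-509C/T	Cirrhosis	50	85	53	57	61	22	C	T	Italy	Caucasian	9	0.190	0.404
Ghani 2019 CHC	-509C/T	CHC	22	47	27	38	42	18	C	T	Pakistan	Asian	9	0.859	0.296
Ghani 2019 HCC	-509C/T	HCC	18	47	29	38	42	18	C	T	Pakistan	Asian	9	0.893	0.296
Hosseini Razavi 2014 CHB	-509C/T	CHB	50	116	54	65	97	58	C	T	Iran	Caucasian	8	0.416	0.082
Kikuchi 2007 PBC	-509C/T	PBC	21	32	12	27	31	13	C	T	Japan	Asian	7	0.975	0.441
Ma 2015 CHC	-509C/T	CHC	91	101	42	143	161	71	C	T	China	Asian	9	0.137	0.036
Ma 2015 HCC	-509C/T	HCC	50	67	42	143	161	71	C	T	China	Asian	9	0.051	0.036
Mohy 2014 Cirrhosis	-509C/T	Cirrhosis	9	21	10	33	4	3	C	T	Egypt	Egyptian	9	0.749	0.001
Oliver 2005 ALD	-509C/T	ALD	64	78	23	79	85	21	C	T	Spain	Caucasian	8	0.921	0.795
Qi 2009 CHB	-509C/T	CHB	31	101	64	50	156	93	C	T	China	Asian	8	0.396	0.257
Qi 2009 HCC	-509C/T	HCC	89	198	92	50	156	93	C	T	China	Asian	8	0.382	0.257
Radwan 2012 Cirrhosis	-509C/T	Cirrhosis	34	74	44	62	68	30	C	T	Egypt	Egyptian	9	0.785	0.147
Radwan 2012 HCC	-509C/T	HCC	24	64	40	62	68	30	C	T	Egypt	Egyptian	9	0.857	0.147
Roy 2012 ALD	-509C/T	ALD	80	75	14	39	48	21	C	T	India	Asian	8	0.539	0.373
Shi 2012 HCC	-509C/T	HCC	24	40	8	55	53	9	C	T	China	Asian	6	0.152	0.438
Wang 2008 Cirrhosis	-509C/T	Cirrhosis	31	53	34	29	50	25	C	T	China	Asian	9	0.272	0.706
Xin 2012 HCC	-509C/T	HCC	82	177	88	212	432	237	C	T	China	Asian	8	0.703	0.583
Saxena 2014 CHB	-509C/T	CHB	8	37	16	44	94	15	C	T	India	Asian	8	0.067	0.001
Saxena 2014 Cirrhosis	-509C/T	Cirrhosis	8	48	4	44	94	15	C	T	India	Asian	8	0.000	0.001
Saxena 2014 HCC	-509C/T	HCC	9	39	11	44	94	15	C	T	India	Asian	8	0.013	0.001
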