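arm	study_id	ancestry	n	prop_women_pct	mean_weight_kg	sd_weight_kg	mean_age_years	sd_age_years	t2d_prev_pct	most_common_glp1	prop_semaglutide_pct
glp1	HUS	EUR	255	68.00	113.70	22.90	53.79	13.52	65.49	Semaglutide	60.40
glp1	ESTBB	EUR	191	62.30	109.18	20.30	56.95	10.96	89.01	Semaglutide	72.77
glp1	UKBB	EUR	614	44.30	105.00	19.90	60.50	7.15	99.80	Liraglutide	0.00
glp1	AoU	EUR	117	64.96	106.66	24.18	57.01	11.03	82.91	Liraglutide	11.97
glp1	AoU	AFR	91	83.52	104.80	25.01	54.57	11.93	92.31	Liraglutide	18.68
glp1	MGBB	EUR	857	57.01	99.99	21.48	59.88	12.17	56.33	Semaglutide	40.72
glp1	MGBB	AFR	156	54.32	104.65	23.80	54.31	11.91	60.24	Dulaglutide	36.14
glp1	BioMe	AMR	614	66.45	91.19	22.45	59.07	11.29	67.75	Dulaglutide	29.32
glp1	BioMe	AFR	728	69.78	101.49	25.42	57.00	12.24	69.50	Dulaglutide	29.12
glp1	BioMe	EUR	369	44.44	98.26	21.93	60.32	11.57	47.97	Semaglutide	37.13
glp1	BioMe	SAS	77	50.65	83.79	20.10	56.48	12.59	70.13	Semaglutide	41.56
glp1	UCLA-ATLAS	AFR	133	64.00	101.60	23.20	61.00	13.00	91.00	Semaglutide	57.10
glp1	UCLA-ATLAS	AMR	336	66.00	94.40	22.60	56.00	13.00	84.00	Liraglutide	26.50
glp1	UCLA-ATLAS	EAS	120	47.00	81.50	16.30	60.00	13.00	92.00	Semaglutide	61.70
glp1	UCLA-ATLAS	EUR	856	53.00	101.60	22.00	63.00	13.00	80.00	Semaglutide	67.80
glp1	QBB	MID	1236	72.17	97.68	24.54	49.52	10.75	75.97	Liraglutide	3.64
bs	HUS	EUR	378	81.00	113.63	19.50	49.90	9.39	37.04
bs	ESTBB	EUR	273	76.56	121.24	20.57	44.72	10.07	28.21
bs	UKBB	EUR	196	69.40	121.00	29.70	55.50	8.21	50.00
bs	AoU	EUR	168	81.55	121.32	29.88	50.74	12.62	18.45
bs	AoU	AFR	183	89.62	127.23	32.55	46.09	11.67	48.63
bs	MGBB	EUR	978	71.06	121.21	26.52	49.37	12.16	39.98
bs	MGBB	AFR	150	86.67	122.89	23.92	43.68	11.67	42.67
bs	BioMe	AMR	143	79.72	112.36	20.81	44.62	11.48	30.07
bs	BioMe	AFR	188	82.98	124.88	25.63	45.35	12.16	29.26
bs	BioMe	EUR	51	70.59	120.23	25.29	49.51	13.34	17.65
bs	QBB	MID	1147	69.49	102.14	23.18	41.66	10.66	40.02
bs	BBSS	EUR	355	56.06	138.48	27.07	47.10	7.11	35.21
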