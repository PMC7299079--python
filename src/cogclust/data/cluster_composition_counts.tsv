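method	item	low_below	low_within	low_above	high_below	high_within	high_above	published_chi2
twostep	MCST_categories	58	69	76	17	26	141	60.56
twostep	MCST_errors	55	82	66	14	61	109	37.17
twostep	CPM47	58	91	54	12	60	112	56.06
twostep	AM	81	64	58	28	64	92	32.62
twostep	ToL_rule_violations	173	27	3	60	112	12	111.52
twostep	ToL_correct_moves	52	147	4	10	124	50	68.82
twostep	ToL_time_violations	167	35	1	43	133	8	135.22
twostep	ToL_total_moves	150	52	1	13	138	33	183.7
twostep	STROOP_time	112	55	36	39	75	70	48.46
twostep	STROOP_errors	64	75	64	20	67	97	29.4
lca	MCST_categories	69	67	48	6	28	169	135.8
lca	MCST_errors	60	82	42	9	61	133	87.38
lca	CPM47	63	92	29	7	59	137	121.64
lca	AM	91	56	37	18	72	113	88.68
lca	ToL_rule_violations	157	25	2	76	114	13	92.50
lca	ToL_correct_moves	47	131	6	15	140	48	48.67
lca	ToL_time_violations	138	45	1	72	123	8	61.62
lca	ToL_total_moves	118	62	4	45	128	30	74.75
lca	STROOP_time	109	40	35	42	90	71	60.40
lca	STROOP_errors	66	58	60	18	84	101	41.80
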