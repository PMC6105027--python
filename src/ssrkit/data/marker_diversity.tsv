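marker	seq_id	na	ne	ho	i	pic
TJIB.Eo_004	TR1654_c2_g1_i1	3	1.88	0.48	0.66	0.36
TJIB.Eo_006	TR2338_c1_g1_i1	10	3.52	0.73	1.41	0.67
TJIB.Eo_008	TR2941_c0_g1_i2	8	5.16	0.83	1.75	0.78
TJIB.Eo_009	TR4044_c0_g1_i1	7	1.40	0.29	0.52	0.26
TJIB.Eo_010	TR5354_c0_g2_i1	11	4.07	0.77	1.65	0.72
TJIB.Eo_013	TR6729_c0_g1_i1	10	2.34	0.59	1.02	0.49
TJIB.Eo_014	TR7108_c0_g1_i1	7	2.59	0.63	1.01	0.54
TJIB.Eo_016	TR7421_c0_g1_i1	5	1.20	0.17	0.31	0.15
TJIB.Eo_017	TR8741_c0_g1_i1	8	3.82	0.76	1.44	0.69
TJIB.Eo_020	TR9728_c0_g2_i1	8	5.27	0.83	1.71	0.78
TJIB.Eo_022	TR11518_c0_g1_i1	7	2.56	0.62	1.14	0.56
TJIB.Eo_023	TR12898_c0_g1_i1	10	5.24	0.83	1.76	0.78
TJIB.Eo_025	TR13845_c0_g1_i1	6	1.90	0.48	0.83	0.42
TJIB.Eo_028	TR14777_c0_g1_i1	5	1.57	0.38	0.55	0.30
TJIB.Eo_029	TR15964_c0_g1_i1	10	2.48	0.61	1.11	0.55
TJIB.Eo_031	TR16281_c0_g1_i1	12	3.36	0.72	1.40	0.65
TJIB.Eo_038	TR18313_c0_g1_i1	11	3.36	0.72	1.34	0.65
TJIB.Eo_040	TR21460_c3_g4_i1	10	3.30	0.71	1.36	0.65
TJIB.Eo_044	TR23987_c0_g1_i1	9	3.38	0.72	1.31	0.65
TJIB.Eo_046	TR26876_c2_g2_i9	11	3.04	0.69	1.22	0.62
TJIB.Eo_047	TR27357_c0_g3_i1	9	4.31	0.79	1.52	0.73
TJIB.Eo_051	TR29033_c0_g3_i1	7	3.74	0.75	1.41	0.69
TJIB.Eo_052	TR29155_c1_g3_i1	13	3.31	0.71	1.26	0.64
TJIB.Eo_054	TR29883_c0_g1_i4	9	2.25	0.57	1.09	0.51
TJIB.Eo_055	TR30407_c0_g1_i1	11	4.68	0.81	1.65	0.76
TJIB.Eo_056	TR30845_c0_g1_i1	9	3.01	0.68	1.28	0.62
TJIB.Eo_060	TR33948_c0_g1_i1	11	2.40	0.60	0.99	0.49
TJIB.Eo_061	TR34533_c0_g3_i1	10	4.50	0.80	1.60	0.74
TJIB.Eo_062	TR34630_c0_g1_i3	7	2.04	0.52	0.81	0.42
TJIB.Eo_063	TR35413_c0_g1_i1	9	1.60	0.39	0.56	0.31
TJIB.Eo_065	TR39482_c0_g1_i1	8	2.98	0.68	1.25	0.60
TJIB.Eo_066	TR39754_c0_g1_i1	10	3.47	0.73	1.35	0.66
TJIB.Eo_068	TR42732_c0_g1_i1	8	2.14	0.55	0.97	0.48
TJIB.Eo_071	TR45627_c0_g1_i1	10	2.62	0.63	1.03	0.55
TJIB.Eo_072	TR46377_c0_g1_i1	10	2.29	0.58	0.98	0.48
TJIB.Eo_073	TR46548_c0_g1_i2	11	1.94	0.50	0.75	0.39
TJIB.Eo_074	TR46887_c0_g3_i1	9	2.86	0.67	1.21	0.59
TJIB.Eo_075	TR46947_c0_g1_i1	8	2.46	0.61	1.04	0.52
TJIB.Eo_077	TR47761_c0_g2_i1	5	1.91	0.49	0.74	0.38
TJIB.Eo_078	TR48071_c1_g1_i2	8	2.65	0.64	1.13	0.57
TJIB.Eo_080	TR51210_c0_g2_i1	9	2.43	0.60	1.21	0.55
TJIB.Eo_082	TR51733_c0_g4_i1	8	3.72	0.75	1.35	0.68
TJIB.Eo_084	TR52704_c4_g2_i1	5	3.07	0.69	1.23	0.61
TJIB.Eo_086	TR53516_c0_g1_i1	9	4.37	0.79	1.62	0.74
TJIB.Eo_087	TR53584_c1_g1_i1	8	5.01	0.82	1.66	0.77
TJIB.Eo_089	TR53936_c0_g1_i1	11	2.70	0.65	1.15	0.57
TJIB.Eo_090	TR54047_c0_g1_i1	4	3.16	0.70	1.25	0.63
TJIB.Eo_091	TR54725_c0_g4_i1	5	2.62	0.63	1.02	0.54
TJIB.Eo_092	TR54851_c2_g5_i1	6	3.07	0.69	1.17	0.61
TJIB.Eo_097	TR59407_c0_g1_i1	5	1.92	0.49	0.97	0.36
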