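subject	group	p1	p2	p3	p4	p5	p6	p7	p8	p9	p10	p11	p12
ccRCC 2	ccRCC	-1.96	-1.48	-0.60	-2.85	-3.33	-0.75	-3.18	-4.35	-3.89	-4.21	-5.91	-6.14
ccRCC 3	ccRCC	-2.39	-2.00	0.37	-3.41	-2.65	-2.05	-3.83	-3.58	-2.50	-5.05	-6.63	-6.24
ccRCC 4	ccRCC	-2.03	-1.16	-2.86	-0.48	-7.09	-0.22	-0.42	-8.50	-4.81	-4.39	-7.48	-4.48
ccRCC 5	ccRCC	-2.10	-2.63	-3.00	1.92	-3.52	0.57	0.58	-3.53	-4.20	-6.72	-3.84	-5.20
ccRCC 6	ccRCC	-3.25	-4.03	-5.03	-6.87	2.14	-3.58	-8.46	2.38	0.20	2.95	2.70	-0.17
ccRCC 7	ccRCC	0.82	-0.44	-1.72	-2.23	-4.49	1.66	-4.30	-3.77	-4.56	-0.93	-3.17	-4.65
ccRCC 8	ccRCC	-5.08	-3.02	-6.18	-0.73	-0.56	-2.62	0.52	-3.16	-3.60	-3.87	-0.68	-1.81
ccRCC 9	ccRCC	-4.15	-1.44	-3.69	-0.60	-1.60	-2.68	1.30	-4.85	-4.19	-5.56	-3.28	-3.31
ccRCC 10	ccRCC	-2.41	-3.35	-5.06	-2.02	-3.62	-4.53	-3.77	-3.22	1.31	-1.03	-2.19	1.65
ccRCC 11	ccRCC	-2.03	0.66	1.07	-5.13	-3.03	-5.93	-3.25	-6.26	-0.92	-3.67	-7.35	-2.70
ccRCC 12	ccRCC	-1.24	-2.49	-6.66	-0.90	-7.25	-1.77	-2.96	-6.54	-1.14	0.62	-3.05	1.66
ccRCC 13	ccRCC	0.87	-2.87	-1.08	-2.55	1.13	-1.67	-7.10	4.33	1.25	-1.20	1.86	-1.91
ccRCC 17	ccRCC	0.90	2.11	0.54	-3.03	-1.73	-3.76	-2.63	-3.48	-1.61	-2.31	-2.59	-1.41
HS 1	HS	0.89	4.48	3.48	-5.50	6.17	-3.84	-2.72	2.04	-3.91	-2.79	2.36	-4.28
HS 2	HS	2.01	-1.47	-2.00	-1.64	0.55	4.80	-5.93	3.49	-5.48	-0.05	3.34	-6.32
HS 3	HS	0.36	-0.92	-0.10	-1.64	2.73	-1.65	-3.73	3.47	-1.23	-3.60	1.97	-3.42
HS 4	HS	1.11	-0.38	1.79	-4.34	2.31	-5.93	-6.64	3.26	3.26	-2.04	0.41	-0.28
HS 5	HS	-3.47	-0.23	-5.80	0.91	0.47	-0.27	3.34	-3.31	-7.13	-4.28	1.58	-2.93
HS 6	HS	1.33	-0.04	0.77	-2.74	5.69	-1.71	-4.92	6.52	-1.08	-2.40	5.03	-3.26
HS 7	HS	-4.06	-2.54	-7.33	0.75	-1.57	-1.60	1.46	-3.63	-4.08	-3.18	0.48	-0.66
HS 8	HS	8.81	1.03	1.76	1.64	-3.12	-0.31	-6.95	4.12	3.93	-0.29	2.71	1.83
HS 9	HS	0.27	1.21	1.57	-0.68	-0.80	-7.32	-0.55	-2.28	2.22	-6.32	-3.32	0.49
HS 10	HS	8.81	-2.11	-7.92	13.50	-13.64	11.52	1.77	-3.26	-4.76	-2.47	1.87	-0.32
HS 11	HS	8.81	-0.54	-0.86	8.67	-2.90	-12.34	-1.49	5.91	17.53	-4.70	5.55	16.48
HS 12	HS	2.23	-0.20	-2.39	-0.95	-5.65	-0.35	-4.19	-3.76	-1.38	-0.13	-2.25	-0.56
HS 13	HS	2.11	0.79	-3.04	-2.01	-0.23	-5.95	-4.14	0.55	3.11	1.46	3.70	5.57
HS 14	HS	-0.55	1.38	-4.46	-1.37	-2.56	-3.01	-0.25	-5.03	-3.08	-0.42	0.13	1.39
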