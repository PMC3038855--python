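# Per-patient t-AML CNA calls (30-patient therapy-related AML cohort),
# transcribed row-for-row from the published cohort table.  Coordinates in Mb
# (10 kb resolution, 1-based inclusive span start-end); ig=1 marks rows the
# source flags with "*" (immunoglobulin/TR-locus VDJ-type deletions).
# Normalized errata: decimal commas ("24,09"); a stray "." in one band span
# ("q42.3.q44"); one missing ">" (t-1).
patient	group	direction	chrom	band_span	start_mb	end_mb	linear_ratio	ig
t-2	t-AML	gain	14	q11.2q12	24.09	26.24	1.23	0
t-2	t-AML	gain	14	q12q13.3	29.52	35.74	1.26	0
t-2	t-AML	gain	14	q21.1q21.2	41.52	44.69	1.23	0
t-2	t-AML	gain	14	q21.3q22.1	47.25	52.51	1.54	0
t-2	t-AML	loss	1	q44	241.94	247.19	0.61	0
t-2	t-AML	loss	5	q14.3q35	85.18	167.84	0.58	0
t-2	t-AML	loss	7	pterp22.3	0.14	2.67	0.65	0
t-2	t-AML	loss	7	p21.3	8.21	11.79	0.64	0
t-2	t-AML	loss	7	p15.2q14.3	27.40	33.28	0.67	0
t-2	t-AML	loss	7	p14.1q33	39.89	135.74	0.63	0
t-2	t-AML	loss	7	q33q34	135.74	137.48	0.16	0
t-2	t-AML	loss	7	q34qter	137.48	158.76	0.60	0
t-2	t-AML	loss	12	p13p11.2	11.27	25.37	0.61	0
t-2	t-AML	loss	12	p11.2q12	32.77	37.09	0.65	0
t-2	t-AML	loss	12	q13.1	47.09	49.44	0.66	0
t-2	t-AML	loss	12	q13.3q22	55.30	92.75	0.63	0
t-2	t-AML	loss	12	q23.3	105.58	107.51	0.68	0
t-2	t-AML	loss	14	q11.2	23.73	24.07	0.70	0
t-2	t-AML	loss	14	q12	26.25	27.10	0.65	0
t-2	t-AML	loss	14	q21.2	35.77	37.62	0.66	0
t-2	t-AML	loss	14	q21.2	44.69	45.26	0.66	0
t-2	t-AML	loss	18	q11.1q11.2	16.79	21.74	0.59	0
t-2	t-AML	loss	18	q11.2q12.1	21.74	24.41	0.22	0
t-2	t-AML	loss	18	q12.1q22.3	24.41	71.05	0.59	0
t-2	t-AML	loss	18	q22.3q23	71.06	71.76	0.23	0
t-2	t-AML	loss	18	q23	71.76	76.11	0.59	0
t-24	t-AML	gain	17	q11.1qter	22.80	78.65	1.39	0
t-24	t-AML	gain	19	p13.3	4.96	6.82	1.44	0
t-24	t-AML	loss	2	p11	89.65	91.05	0.62	1
t-24	t-AML	loss	17	pterp11.2	0.28	21.22	0.63	0
t-24	t-AML	loss	19	p13.3	0.21	4.96	0.60	0
t-8	t-AML	gain	13	q11qter	18.36	114.10	1.46	0
t-8	t-AML	loss	7	q31.1q36.1	107.67	150.28	0.55	0
t-8	t-AML	loss	21	q22.1	35.01	35.60	0.11	0
t-8	t-AML	loss	X	p11.4	39.25	39.85	0.16	0
t-13	t-AML	gain	2	p16.1p25.3	0.02	54.88	1.46	0
t-13	t-AML	loss	1	q42.3q44	233.13	247.19	0.53	0
t-13	t-AML	loss	10	q11.2	45.53	47.97	0.78	0
t-30	t-AML	loss	2	p23.3	25.31	25.60	0.50	0
t-30	t-AML	loss	14	q32.3	105.96	106.00	0.65	1
t-15	t-AML	gain	8	pterqter	0.16	146.26	1.31	0
t-15	t-AML	gain	17	pterqter	0.02	78.65	1.31	0
t-15	t-AML	loss	2	p11	88.98	91.05	0.46	1
t-15	t-AML	loss	4	q31.2	146.62	146.67	0.68	0
t-15	t-AML	loss	14	q32.3	105.40	106.15	0.34	1
t-4	t-AML	gain	2	q14.3q32.3	128.11	193.87	1.34	0
t-4	t-AML	gain	7	q11.2q36.3	61.46	158.81	1.65	0
t-4	t-AML	gain	12	p12.1p11.2	24.32	30.60	1.37	0
t-4	t-AML	loss	1	p36.11	26.73	27.04	0.64	0
t-4	t-AML	loss	1	q43	237.92	238.50	0.62	0
t-4	t-AML	loss	5	q31.1q33.1	142.91	148.19	0.63	0
t-4	t-AML	loss	7	p11.1p22.3	0.14	57.89	0.65	0
t-4	t-AML	loss	12	pterp12.1	0.05	21.96	0.63	0
t-4	t-AML	loss	14	q32.3	105.13	105.84	0.68	1
t-4	t-AML	loss	15	q11.2q21.3	20.24	55.80	0.65	0
t-4	t-AML	loss	17	p13.3p11.2	0.02	22.07	0.65	0
t-4	t-AML	loss	17	q22	51.84	54.75	0.64	0
t-16	t-AML	gain	7	p15.2	27.15	27.18	1.33	0
t-16	t-AML	gain	8	q24.2q24.3	139.48	140.18	1.46	0
t-23	t-AML	gain	4	q35.1q35.2	187.17	187.37	1.49	0
t-23	t-AML	loss	14	q32.3	106.21	106.25	0.66	1
t-17	t-AML	gain	7	p15.2	27.15	27.18	1.26	0
t-17	t-AML	gain	6	q27	168.12	168.84	1.20	0
t-17	t-AML	loss	2	p11	89.10	89.89	0.70	1
t-17	t-AML	loss	3	p12.3p14.1	69.07	79.19	0.54	0
t-17	t-AML	loss	14	q32.3	105.85	105.89	0.59	1
t-29	t-AML	loss	14	q32.3	105.94	106.00	0.66	1
t-29	t-AML	loss	21	q22.1	34.98	35.29	0.59	0
t-3	t-AML	gain	8	q24.3	143.73	143.90	1.50	0
t-3	t-AML	loss	14	q32.3	104.96	105.22	0.76	1
t-26	t-AML	gain	2	q11.2	98.43	98.63	1.42	0
t-12	t-AML	gain	21	q22.1qter	35.07	46.91	1.19	0
t-12	t-AML	loss	7	q22.1q36.3	101.85	158.79	0.80	0
t-9	t-AML	gain	4	p16.3	1.20	1.30	1.38	0
t-9	t-AML	gain	6	q27	168.08	168.32	1.50	0
t-9	t-AML	loss	7	pterqter	0.14	158.76	0.56	0
t-11	t-AML	loss	21	q22.12	35.11	35.15	0.68	0
t-14	t-AML	gain	7	p15.2	27.15	27.18	1.38	0
t-14	t-AML	gain	8	pterq24.3	0.16	142.23	1.35	0
t-14	t-AML	gain	8	q24.3	142.23	145.81	1.52	0
t-14	t-AML	gain	8	q24.3	145.81	146.26	1.35	0
t-14	t-AML	loss	14	q32.3	105.96	106.00	0.60	1
t-14	t-AML	loss	17	q11.2	25.96	27.38	0.72	0
t-1	t-AML	loss	5	q15qter	94.36	177.87	0.79	0
t-5	t-AML	gain	5	p15.2p14.3	10.78	21.71	1.27	0
t-5	t-AML	gain	5	p13.3q11.2	31.24	53.59	1.31	0
t-5	t-AML	gain	21	q22.1	36.40	36.53	1.60	0
t-5	t-AML	loss	3	p14.1p12.3	69.67	80.18	0.54	0
t-5	t-AML	loss	5	pterp15.2	0.09	10.76	0.57	0
t-5	t-AML	loss	5	q12.3qter	65.23	180.64	0.57	0
t-5	t-AML	loss	7	pterp11.1	0.14	57.66	0.57	0
t-5	t-AML	loss	7	q21.3q36.3	97.13	158.76	0.57	0
t-5	t-AML	loss	12	p13.2p13.1	11.82	13.33	0.62	0
t-10	t-AML	gain	1	q44	246.44	247.06	1.32	0
t-10	t-AML	loss	7	p22.2	3.02	3.12	0.48	0
t-10	t-AML	loss	7	q11.2	64.40	75.85	0.77	0
t-10	t-AML	loss	7	q21.3q22.1	97.69	101.88	0.77	0
t-7	t-AML	gain	9	q34.3	135.98	139.80	1.30	0
t-7	t-AML	gain	12	p13.1	14.25	14.61	1.36	0
t-7	t-AML	gain	12	p11.1	31.55	34.64	1.34	0
t-7	t-AML	gain	12	q13.1q14.3	47.69	51.83	1.42	0
t-7	t-AML	gain	12	q14.1q14.3	58.80	64.31	1.33	0
t-7	t-AML	gain	21	q21.2q21.3	23.17	30.35	1.42	0
t-7	t-AML	gain	21	q22.1q22.3	36.20	43.01	1.58	0
t-7	t-AML	loss	7	pterqter	0.14	158.81	0.79	0
t-7	t-AML	loss	12	q12	36.73	42.14	0.65	0
t-7	t-AML	loss	12	q13.1	45.33	47.69	0.68	0
t-7	t-AML	loss	17	pterp11.3	0.02	21.23	0.78	0
t-7	t-AML	loss	21	q21.1q21.2	19.84	23.05	0.65	0
t-7	t-AML	loss	21	q22.1	34.38	36.12	0.66	0
t-7	t-AML	loss	21	q22.3	43.02	43.08	0.65	0
t-6	t-AML	loss	7	pterqter	0.14	158.76	0.70	0
t-22	t-AML	gain	2	p25.2	2.54	3.57	1.37	0
t-22	t-AML	gain	8	pterqter	0.16	146.26	1.40	0
t-19	t-AML	gain	7	p15.2	27.15	27.18	1.40	0
t-18	t-AML	loss	14	q32.3	105.94	106.00	0.64	1
t-25	t-AML	loss	2	p11	89.10	91.05	0.69	1
t-25	t-AML	loss	14	q32.3	105.96	106.00	0.61	1
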