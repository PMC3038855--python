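# Per-patient p-AML CNA calls (36-patient de novo AML cohort), transcribed
# row-for-row from the published cohort table; same conventions as the t-AML
# table.  Normalized errata: decimal commas (p-22, p-32); "<56.84.18-67.10>"
# read as 56.84; "<35.86 = 37.20>" read as 35.86-37.20; "<105.60-105-70>"
# read as 105.60-105.70; p-25 "<105.96-105.94>" start/end swapped back.
patient	group	direction	chrom	band_span	start_mb	end_mb	linear_ratio	ig
p-24	p-AML	gain	1	p36.3	1.52	7.56	1.26	0
p-24	p-AML	gain	1	q21q22	153.19	154.64	1.67	0
p-24	p-AML	gain	3	p21.3	50.26	50.29	2.54	0
p-24	p-AML	gain	3	p21.3	52.29	52.31	4.00	0
p-24	p-AML	gain	4	p16.3	0.99	1.65	1.61	0
p-24	p-AML	gain	15	q22.2q23	56.84	67.10	2.05	0
p-24	p-AML	gain	15	q23	67.44	68.37	3.64	0
p-24	p-AML	gain	15	q24.1	70.42	72.67	2.89	0
p-24	p-AML	gain	15	q24.1q26.2	72.70	94.54	1.30	0
p-24	p-AML	gain	16	q23.3q24.3	82.61	88.67	1.80	0
p-24	p-AML	gain	19	p13.3p13.1	0.64	19.72	1.41	0
p-24	p-AML	gain	20	p12.3p13	0.27	9.14	1.26	0
p-24	p-AML	gain	21	q22.1	33.30	37.23	1.79	0
p-24	p-AML	gain	21	q22.1	37.24	38.54	2.50	0
p-24	p-AML	gain	21	q22.1	38.54	39.38	3.00	0
p-24	p-AML	gain	21	q22.2q22.3	39.40	43.22	2.18	0
p-24	p-AML	gain	21	q22.3	43.23	46.89	1.70	0
p-24	p-AML	gain	22	q13.1	35.86	37.20	1.33	0
p-24	p-AML	loss	2	pterp22.3	0.02	32.60	0.66	0
p-24	p-AML	loss	2	p14p13.3	68.01	71.72	0.66	0
p-24	p-AML	loss	2	q35qter	219.02	242.39	0.66	0
p-24	p-AML	loss	3	p22p21.3	38.35	49.66	0.66	0
p-24	p-AML	loss	5	q14.2q33.3	82.18	158.75	0.61	0
p-24	p-AML	loss	7	p15.2p15.3	19.64	26.31	0.63	0
p-24	p-AML	loss	7	q11.22q11.23	69.84	72.44	0.65	0
p-24	p-AML	loss	7	q21.12q22.2	87.65	105.96	0.71	0
p-24	p-AML	loss	7	q31.32q36.3	123.35	158.81	0.64	0
p-24	p-AML	loss	14	q32.3	105.60	105.70	0.74	1
p-24	p-AML	loss	15	q26.2q26.3	94.55	100.21	0.75	0
p-24	p-AML	loss	16	p13.3q23.1	15.38	78.80	0.74	0
p-24	p-AML	loss	17	p11.2q12	0.18	29.54	0.65	0
p-24	p-AML	loss	17	q21.3q21.33	38.29	46.94	0.66	0
p-21	p-AML	gain	3	p14.3p14.2	57.97	62.19	1.48	0
p-21	p-AML	gain	3	p14.2p14.1	63.60	64.29	1.31	0
p-21	p-AML	gain	3	p14.1	64.32	65.50	4.61	0
p-21	p-AML	gain	3	p14.1	66.40	67.67	4.71	0
p-21	p-AML	gain	3	p11.2qter	89.28	199.32	1.35	0
p-21	p-AML	gain	21	q11.2q21.1	14.29	17.97	5.46	0
p-21	p-AML	gain	21	q22.1q22.3	38.27	43.54	5.45	0
p-21	p-AML	gain	21	q22.3	43.59	45.12	2.11	0
p-21	p-AML	gain	21	q22.3qter	45.12	46.91	1.70	0
p-21	p-AML	loss	1	q21.1q44	147.21	247.19	0.62	0
p-21	p-AML	loss	2	p11.2	89.38	91.05	0.61	1
p-21	p-AML	loss	2	pterp24.3	0.02	16.22	0.61	0
p-21	p-AML	loss	3	p24.3p14.3	0.03	57.40	0.63	0
p-21	p-AML	loss	3	p14.2	62.20	63.58	0.60	0
p-21	p-AML	loss	3	p14.1	65.51	66.11	0.60	0
p-21	p-AML	loss	3	p14.1p12.1	67.68	86.30	0.67	0
p-21	p-AML	loss	4	q22.1q27	88.94	123.72	0.61	0
p-21	p-AML	loss	9	q22.3q31.1	93.92	103.86	0.63	0
p-22	p-AML	loss	4	q28.2q28.3	130.24	134.36	0.55	0
p-22	p-AML	loss	12	p12.1p13.2	11.40	21.20	0.55	0
p-22	p-AML	loss	18	q21.2	48.99	51.05	0.55	0
p-22	p-AML	loss	18	q22.3q23	69.56	76.03	0.55	0
p-23	p-AML	gain	1	q23.2qter	158.48	247.17	1.24	0
p-5	p-AML	gain	4	pterqter	0.06	191.02	1.43	0
p-32	p-AML	loss	3	p21.3	44.20	49.02	0.59	0
p-6	p-AML	gain	1	q32.1qter	201.31	247.10	1.39	0
p-1	p-AML	loss	7		0.14	158.76	0.61	0
p-2	p-AML	gain	X	p22.2	15.95	16.61	2.04	0
p-2	p-AML	loss	7		0.14	158.76	0.55	0
p-2	p-AML	loss	22	q11.2	21.36	21.41	0.52	0
p-7	p-AML	gain	11	q24.2qter	124.85	134.43	1.23	0
p-7	p-AML	loss	7	q31.2qter	115.49	158.78	0.77	0
p-3	p-AML	gain	8	pterqter	0.16	146.25	1.27	0
p-3	p-AML	gain	13	pterqter	18.31	114.12	1.28	0
p-3	p-AML	loss	2	p11.2	88.93	89.14	0.69	1
p-18	p-AML	loss	8	q21.3q22.1	93.15	94.17	0.63	0
p-18	p-AML	loss	9	q12q31.1	67.20	104.45	0.62	0
p-13	p-AML	gain	17	q21.2	35.76	35.84	1.49	0
p-4	p-AML	gain	21	q11.2qter	14.31	46.91	1.77	0
p-19	p-AML	loss	14	q32.3	105.02	105.04	0.76	1
p-25	p-AML	loss	14	q32.3	105.94	105.96	0.61	1
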