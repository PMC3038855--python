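# Published minimal-critical-region catalog for the two cohorts (transcribed
# as printed, including the printed Size column even where it disagrees with
# the printed bounds for some p-AML rows).  amp=1 marks rows annotated "Amp".
group	direction	chrom	band_span	start_mb	end_mb	size_mb	patients	amp
t-AML	loss	1	q44	241.94	247.19	5.25	t-2,t-13	0
t-AML	loss	3	p14.1p12.3	69.67	79.19	9.52	t-5,t-17	0
t-AML	loss	5	q31.3q33.1	142.91	148.19	5.28	t-1,t-2,t-4,t-5	0
t-AML	gain	6	q27	168.12	168.32	0.20	t-9,t-17	0
t-AML	loss	7	p22.2	3.02	3.12	0.10	t-5,t-6,t-7,t-9,t-10	0
t-AML	gain	7	p15.2	27.15	27.18	0.03	t-14,t-16,t-17,t-19	0
t-AML	loss	7	q21.3	97.69	101.88	4.19	t-2,t-5,t-6,t-7,t-9,t-10	0
t-AML	loss	7	q33q34	135.74	137.48	1.74	t-2,t-5,t-6,t-7,t-8,t-9	0
t-AML	gain	8	q24.3	143.73	143.90	0.17	t-3,t-14	0
t-AML	loss	12	p13.2p13.1	11.82	13.33	1.51	t-2,t-4,t-5	0
t-AML	gain	17	q21.3	22.80	78.65	55.85	t-15,t-24	0
t-AML	loss	21	q22.1	35.11	35.15	0.04	t-7,t-8,t-11,t-29	0
p-AML	gain	1	q21q22	153.19	154.64	1.40	p-23,p-24	0
p-AML	gain	1	q32.1q44	201.31	247.19	45.69	p-6,p-23	0
p-AML	loss	3	p21.3	44.20	49.02	5.18	p-21,p-24,p-32	0
p-AML	loss	7	q31.2q36.3	115.49	158.78	43.29	p-1,p-2,p-7	0
p-AML	loss	9	q22.3q31.1	93.92	103.96	9.81	p-18,p-21	0
p-AML	gain	21	q21.1	14.29	17.97	3.78	p-4,p-21	1
p-AML	gain	21	q22.2	38.27	43.54	5.25	p-4,p-21,p-24	1
p-AML	gain	21	q22.3qter	43.54	46.91	7.49	p-4,p-21,p-24	0
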