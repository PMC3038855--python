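# Cohort membership and constitutional karyotype prefix (sex-chromosome
# complement) per patient, from the published clinical tables.
patient	group	prefix
t-1	t-AML	46,XX
t-2	t-AML	46,XX
t-3	t-AML	46,XX
t-4	t-AML	46,XX
t-5	t-AML	46,XY
t-6	t-AML	46,XY
t-7	t-AML	46,XY
t-8	t-AML	46,XY
t-9	t-AML	46,XY
t-10	t-AML	46,XY
t-11	t-AML	46,XY
t-12	t-AML	46,XY
t-13	t-AML	46,XX
t-14	t-AML	46,XX
t-15	t-AML	46,XX
t-16	t-AML	46,XX
t-17	t-AML	46,XX
t-18	t-AML	46,XX
t-19	t-AML	46,XX
t-20	t-AML	46,XX
t-21	t-AML	46,XX
t-22	t-AML	46,XY
t-23	t-AML	46,XX
t-24	t-AML	46,XX
t-25	t-AML	46,XX
t-26	t-AML	46,XX
t-27	t-AML	46,XX
t-28	t-AML	46,XX
t-29	t-AML	46,XY
t-30	t-AML	46,XY
p-1	p-AML	46,XX
p-2	p-AML	46,XY
p-3	p-AML	46,XY
p-4	p-AML	46,XX
p-5	p-AML	46,XY
p-6	p-AML	46,XX
p-7	p-AML	46,XY
p-8	p-AML	46,XX
p-9	p-AML	46,XX
p-10	p-AML	46,XX
p-11	p-AML	46,XY
p-12	p-AML	46,XY
p-13	p-AML	46,XY
p-14	p-AML	46,XY
p-15	p-AML	46,XY
p-16	p-AML	46,XY
p-17	p-AML	46,XY
p-18	p-AML	46,XY
p-19	p-AML	46,XY
p-20	p-AML	46,XY
p-21	p-AML	46,XY
p-22	p-AML	46,XY
p-23	p-AML	46,XY
p-24	p-AML	46,XY
p-25	p-AML	46,XX
p-26	p-AML	46,XX
p-27	p-AML	46,XX
p-28	p-AML	46,XX
p-29	p-AML	46,XX
p-30	p-AML	46,XX
p-31	p-AML	46,XY
p-32	p-AML	46,XY
p-33	p-AML	46,XY
p-34	p-AML	46,XY
p-35	p-AML	46,XY
p-36	p-AML	46,XY
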