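# Synthetic approximate cytoband map (hg18-like), UCSC cytoBand format (0-based half-open).
# Author-constructed: band boundaries are approximate and tile each chromosome; not the UCSC file.
1	0	41430000	p15	gneg
1	41430000	82870000	p13	gneg
1	82870000	124300000	p11	gneg
1	124300000	155040000	q11	gneg
1	155040000	185770000	q21	gneg
1	185770000	216510000	q23	gneg
1	216510000	247249719	q25	gneg
2	0	31100000	p15	gneg
2	31100000	62200000	p13	gneg
2	62200000	93300000	p11	gneg
2	93300000	130710000	q11	gneg
2	130710000	168130000	q21	gneg
2	168130000	205540000	q23	gneg
2	205540000	242951149	q25	gneg
3	0	30570000	p15	gneg
3	30570000	61130000	p13	gneg
3	61130000	91700000	p11	gneg
3	91700000	118650000	q11	gneg
3	118650000	145600000	q21	gneg
3	145600000	172550000	q23	gneg
3	172550000	199501827	q25	gneg
4	0	16800000	p15	gneg
4	16800000	33600000	p13	gneg
4	33600000	50400000	p11	gneg
4	50400000	85620000	q11	gneg
4	85620000	120840000	q21	gneg
4	120840000	156050000	q23	gneg
4	156050000	191273063	q25	gneg
5	0	15900000	p15	gneg
5	15900000	31800000	p13	gneg
5	31800000	47700000	p11	gneg
5	47700000	80990000	q11	gneg
5	80990000	114280000	q21	gneg
5	114280000	147570000	q23	gneg
5	147570000	180857866	q25	gneg
6	0	20170000	p15	gneg
6	20170000	40330000	p13	gneg
6	40330000	60500000	p11	gneg
6	60500000	88100000	q11	gneg
6	88100000	115700000	q21	gneg
6	115700000	143300000	q23	gneg
6	143300000	170899992	q25	gneg
7	0	7200000	p22	gpos50
7	7200000	16300000	p21	gneg
7	16300000	28000000	p15	gneg
7	28000000	45000000	p14	gpos50
7	45000000	54000000	p12	gpos50
7	54000000	59100000	p11	gneg
7	59100000	72000000	q11.2	gpos50
7	72000000	98000000	q21	gneg
7	98000000	107400000	q22	gpos50
7	107400000	127500000	q31	gneg
7	127500000	132600000	q32	gpos50
7	132600000	136700000	q33	gneg
7	136700000	143000000	q34	gpos50
7	143000000	148400000	q35	gneg
7	148400000	158821424	q36	gpos50
8	0	15070000	p15	gneg
8	15070000	30130000	p13	gneg
8	30130000	45200000	p11	gneg
8	45200000	70470000	q11	gneg
8	70470000	95740000	q21	gneg
8	95740000	121010000	q23	gneg
8	121010000	146274826	q25	gneg
9	0	16270000	p15	gneg
9	16270000	32530000	p13	gneg
9	32530000	48800000	p11	gneg
9	48800000	71670000	q11	gneg
9	71670000	94540000	q21	gneg
9	94540000	117400000	q23	gneg
9	117400000	140273252	q25	gneg
10	0	13430000	p15	gneg
10	13430000	26870000	p13	gneg
10	26870000	40300000	p11	gneg
10	40300000	64070000	q11	gneg
10	64070000	87840000	q21	gneg
10	87840000	111610000	q23	gneg
10	111610000	135374737	q25	gneg
11	0	17630000	p15	gneg
11	17630000	35270000	p13	gneg
11	35270000	52900000	p11	gneg
11	52900000	73290000	q11	gneg
11	73290000	93680000	q21	gneg
11	93680000	114060000	q23	gneg
11	114060000	134452384	q25	gneg
12	0	11800000	p15	gneg
12	11800000	23600000	p13	gneg
12	23600000	35400000	p11	gneg
12	35400000	59640000	q11	gneg
12	59640000	83870000	q21	gneg
12	83870000	108110000	q23	gneg
12	108110000	132349534	q25	gneg
13	0	5330000	p15	gneg
13	5330000	10670000	p13	gneg
13	10670000	16000000	p11	gneg
13	16000000	40540000	q11	gneg
13	40540000	65070000	q21	gneg
13	65070000	89610000	q23	gneg
13	89610000	114142980	q25	gneg
14	0	5000000	p13	gneg
14	5000000	9000000	p12	gpos50
14	9000000	15600000	p11	gneg
14	15600000	23600000	q11.2	gpos50
14	23600000	32000000	q12	gpos50
14	32000000	46800000	q21	gneg
14	46800000	56000000	q22	gpos50
14	56000000	62000000	q23	gneg
14	62000000	73000000	q24	gpos50
14	73000000	84000000	q31	gneg
14	84000000	95000000	q32.1	gneg
14	95000000	102000000	q32.2	gpos50
14	102000000	106368585	q32.3	gneg
15	0	5270000	p15	gneg
15	5270000	10530000	p13	gneg
15	10530000	15800000	p11	gneg
15	15800000	36930000	q11	gneg
15	36930000	58070000	q21	gneg
15	58070000	79200000	q23	gneg
15	79200000	100338915	q25	gneg
16	0	12730000	p15	gneg
16	12730000	25470000	p13	gneg
16	25470000	38200000	p11	gneg
16	38200000	50860000	q11	gneg
16	50860000	63510000	q21	gneg
16	63510000	76170000	q23	gneg
16	76170000	88827254	q25	gneg
17	0	7400000	p15	gneg
17	7400000	14800000	p13	gneg
17	14800000	22200000	p11	gneg
17	22200000	36340000	q11	gneg
17	36340000	50490000	q21	gneg
17	50490000	64630000	q23	gneg
17	64630000	78774742	q25	gneg
18	0	5370000	p15	gneg
18	5370000	10730000	p13	gneg
18	10730000	16100000	p11	gneg
18	16100000	31100000	q11	gneg
18	31100000	46110000	q21	gneg
18	46110000	61110000	q23	gneg
18	61110000	76117153	q25	gneg
19	0	9500000	p15	gneg
19	9500000	19000000	p13	gneg
19	19000000	28500000	p11	gneg
19	28500000	37330000	q11	gneg
19	37330000	46160000	q21	gneg
19	46160000	54980000	q23	gneg
19	54980000	63811651	q25	gneg
20	0	9030000	p15	gneg
20	9030000	18070000	p13	gneg
20	18070000	27100000	p11	gneg
20	27100000	35930000	q11	gneg
20	35930000	44770000	q21	gneg
20	44770000	53600000	q23	gneg
20	53600000	62435964	q25	gneg
21	0	2900000	p13	gneg
21	2900000	6300000	p12	gpos50
21	6300000	9800000	p11.2	gpos50
21	9800000	13200000	p11.1	gneg
21	13200000	14300000	q11.1	gneg
21	14300000	16300000	q11.2	gpos50
21	16300000	24000000	q21.1	gneg
21	24000000	27000000	q21.2	gpos50
21	27000000	31500000	q21.3	gneg
21	31500000	35000000	q22.11	gneg
21	35000000	36400000	q22.12	gpos50
21	36400000	37500000	q22.13	gneg
21	37500000	39700000	q22.2	gpos50
21	39700000	46944323	q22.3	gneg
22	0	4900000	p15	gneg
22	4900000	9800000	p13	gneg
22	9800000	14700000	p11	gneg
22	14700000	23450000	q11	gneg
22	23450000	32200000	q21	gneg
22	32200000	40940000	q23	gneg
22	40940000	49691432	q25	gneg
X	0	19830000	p15	gneg
X	19830000	39670000	p13	gneg
X	39670000	59500000	p11	gneg
X	59500000	83350000	q11	gneg
X	83350000	107210000	q21	gneg
X	107210000	131060000	q23	gneg
X	131060000	154913754	q25	gneg
Y	0	3770000	p15	gneg
Y	3770000	7530000	p13	gneg
Y	7530000	11300000	p11	gneg
Y	11300000	22920000	q11	gneg
Y	22920000	34540000	q21	gneg
Y	34540000	46150000	q23	gneg
Y	46150000	57772954	q25	gneg
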