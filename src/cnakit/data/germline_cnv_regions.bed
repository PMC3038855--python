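# Known germline copy-number-variant regions (BED, 0-based half-open),
# standing in for a Database of Genomic Variants extract; derived from the
# published germline-CNV table of the same cohorts.
1	16710000	17140000	1p36.13_CROCC
1	150820000	150840000	1q21.3_NLCE3C
1	159750000	159900000	1q23.3_FCGR
1	246790000	246860000	1q44_OR2T
3	196900000	196960000	3q29_MUC20
4	69050000	69160000	4q13.2_UGT2B17
5	760000	870000	5p15.33_ZDHHC11
6	200000	320000	6p25.3_DUSP22
6	32560000	32720000	6p21.2_HLA-DRB
8	39350000	39500000	8p11.3_ADAM3A
10	46370000	47730000	10q11.22_ANXA8
11	55120000	55200000	11q11_OR4
12	19360000	19460000	12p12_PLEKHA5
14	18620000	19490000	14q11.2_OR4K
15	18650000	20080000	15q11.2_NF1P1_BCL8
15	32510000	32620000	15q14_GOLGA8B
16	31860000	33530000	16p11.2_TP53TG3
17	41520000	41570000	17q21.31_KIAA1267
17	41550000	42040000	17q21.31_NSF
19	48200000	48430000	19q13.2_PSG
22	22650000	22720000	22q11.23_GSTT1
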