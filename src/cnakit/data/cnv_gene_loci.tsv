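# Gene loci whose involvement marks a small recurrent call as a likely
# germline CNV (olfactory-receptor clusters, the NF1P1/BCL8 locus, GSTT1).
name	chrom	start_mb	end_mb
OR2T_1q44	1	246.79	246.86
OR4_11q11	11	55.12	55.20
OR4K_14q11.2	14	18.62	19.49
NF1P1_15q11.2	15	18.65	20.08
GSTT1_22q11.23	22	22.65	22.72
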