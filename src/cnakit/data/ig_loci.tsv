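# Immunoglobulin / T-cell-receptor locus extents (Mb, approximate) used to
# flag VDJ-rearrangement-type focal deletions.  Extents are widened relative
# to the germinal-CNV table so that every published asterisked deletion of
# the cohorts is contained (IGK distal V cluster, IGH 3' end); IGL placement
# is approximate.
name	chrom	band	start_mb	end_mb
IGK	2	p11.2	88.90	91.10
TRG	7	p14.1	38.22	38.41
TRA/TRD	14	q11.2	21.43	22.04
IGH	14	q32.33	104.90	106.30
IGL	22	q11.22	21.57	22.55
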