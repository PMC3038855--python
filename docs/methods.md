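# Methods

`cnakit` analyses two-color array-CGH copy-number data from leukemia
cohorts.  This note documents the models, the parameters that matter, the
synthetic-data generator, and the design choices taken where the underlying
procedures were open.

## Signal model

A probe measures the log2 ratio of tumor to reference DNA.  For an event
with integer copy number `c` present in a clonal (blast) fraction `f` of
cells, against a diploid reference, the expected linear ratio is

    r(c, f) = 1 + f·(c/2 − 1)

so a heterozygous loss (`c = 1`) at `f = 0.8` gives `r = 0.6`, and observed
cohort ratios for monosomies (0.55–0.80) correspond to blast fractions of
roughly 0.4–0.9.  Probe noise is additive Gaussian on the log2 scale.
Samples hybridized as dye-swap pairs are combined probe-wise as
`(forward − reverse)/2`, which cancels dye bias and reduces noise variance
by half; probes whose forward and negated-reverse values differ by more
than `dye_swap_discordance_tol` (default 0.5 log2 units) are excluded as
dye artifacts.

## Coordinates and rounding

Intervals are stored 1-based inclusive in base pairs.  The cohort tables
print positions in Mb at 10 kb resolution, so `<85.18–167.84>` maps to
`[85 180 001, 167 840 000]` bp and its printed size is exactly
`end − start` Mb.  All Mb reporting rounds half-up to 2 decimals.  BED
import/export converts to 0-based half-open in one place
(`GenomicInterval.to_bed` and the BED readers).  Overlap means at least one
shared base; touching intervals do not overlap.  The packaged genome model
is hg18; any `chrom.sizes` file can replace it.

## Segment detection

The original arrays were segmented with a proprietary detection algorithm
whose internals are not public; `cnakit` implements a documented stand-in
and treats the published *post-filter* as the reproducible contract:
aberrations keep segments with **≥ 5 probes** and **|mean log2| > 0.3**
(both strict as printed), minus segments overlapping an artifact mask
(high-copy repeats, GC-rich and telomeric regions; default mask = terminal
100 kb of every chromosome, configurable) by ≥ 50% of their length.

The stand-in is deterministic recursive segmentation.  For a segment of
`m` probes two candidate cuts are scored by the drop in residual sum of
squares:

* the best **binary split** `k`, gain `k(m−k)/m · (μ_L − μ_R)²`;
* the best **interior carve-out** of length ≤ 256 probes, scored against
  its complement (the circular-segmentation statistic restricted to short
  windows).  A plain binary split is nearly blind to a short aberrant run
  deep inside a long segment — an 8-probe implant moves the flank means by
  almost nothing — which is why short interior windows are scanned
  explicitly; events longer than 256 probes shift the flank means enough
  for binary splits to find them.

The better of the two cuts is accepted when `gain/σ̂² > penalty`, with
`penalty = 10·log(n)` per chromosome by default (a BIC-style constant) and
`σ̂` the robust noise scale from the median absolute probe-to-probe
difference (`σ̂ = 1.4826·MAD/√2`), which is immune to the copy-number
signal itself.  Accepted cuts recurse; afterwards adjacent segments whose
means differ by less than `merge_mean_tol` (default 0.1 log2) are
re-merged.  There are no permutation p-values; fixed input and parameters
give identical output.

Measured behavior under the defaults (see the test suite, which runs these
numbers): implants of ≥ 8 probes and |log2| ≥ 0.5 in sd-0.15 noise are
recovered with breakpoint error ≤ 2 probes in 100% of 200 runs of 1000
probes; 100 pure-noise profiles of 10 000 probes average zero surviving
calls after filtering.

## Copy-state classification

Linear ratio maps to state with thresholds inclusive on the aberrant side:
`≥ 4` high amplification, `[2, 4)` low amplification, `[1.2, 2)` gain,
`(0.8, 1.2)` neutral, `[0.25, 0.8]` loss, `< 0.25` deep (near-homozygous)
loss.  The printed low-amplification bound "between <2 and <4" is read as
the half-open band `[2, 4)` (the stray `<` treated as a typo).  Cohort
table rows printed at 2 decimals can fall marginally on the neutral side
of a threshold (one gain is printed `[1.19]`); when a row carries an
explicit sign, the sign decides gain/loss for such borderline ratios.

## Germline CNV and IG filtering

Without a matched normal, germline copy-number variants must be separated
from acquired abnormalities by rules:

* **Database overlap is individually sufficient**: reciprocal overlap
  ≥ 0.5 with a known-CNV region (the packaged file stands in for a genomic
  variants database extract).
* Otherwise three criteria must **co-occur**: size < 2 Mb, identical
  breakpoints (± one 10 kb reporting unit) in another patient's
  same-direction call, and involvement of a configured CNV-prone gene
  locus (olfactory-receptor clusters, NF1P1, GSTT1).  Shared breakpoints
  alone must not flag: the recurrent 30 kb 7p15.2 HOXA-cluster gain has
  identical breakpoints in four patients and is a genuine somatic lesion.

**IG/TR deletions** (VDJ-rearrangement footprints in IGK/IGH/IGL/TRG/TRA)
mark the malignant clone, not a driver; they are flagged and excluded from
CNA counting and MCR derivation but kept for the clonality statistic.
Only **losses** qualify, and the call must lie essentially **inside** one
configured locus (≥ 90% containment).  Containment, not mere overlap, is
deliberate: a monosomy 7 sweeps across the TRG locus yet is obviously not
a VDJ rearrangement.  The packaged locus extents are approximate and
widened relative to the germline-CNV table so that every transcribed
asterisked deletion of the cohorts is contained (the IGK distal V-cluster
and the IGH 3′ end extend beyond the printed germline intervals); re-running
the rule from scratch on the packaged tables reproduces the transcribed
flags exactly (test-asserted).

## Minimal critical regions

An MCR is the smallest interval shared by same-direction CNAs of ≥ 2
patients.  The derivation is a seeded-intersection fixpoint: every call
seeds a candidate; co-localizing same-direction calls from other patients
are intersected into it in ascending (size, patient id) order, skipping
calls that no longer co-localize at their turn (one ordered pass reaches
the fixpoint because intersection only shrinks).  Support is counted at
patient level; gains and amplifications pool as direction "gain", with an
amplification flag carried when any supporter is in an amplified state.
Identical candidates deduplicate (larger support wins, then lexicographic
patient set, then seed id), and a candidate strictly containing another
candidate with superset-or-equal support is pruned.

A call **co-localizes** when the shared span covers ≥ 50% of the smaller
of the two intervals (`min_member_overlap`, 0 restores plain any-overlap).
This guard is load-bearing: one patient's 57 Mb distal-7q loss clips a
4.2 Mb recurrent 7q21.3 region by 30 kb, and under plain overlap the
candidate collapses to the 30 kb sliver; the published catalog treats such
marginal edge-clippers as not co-localizing, and with the guard the
derivation reproduces all 12 published therapy-related-cohort regions with
identical bounds at 10 kb resolution (test-asserted).  The candidate set
is a *superset* of the published catalog, which was curated by hand — for
example a recurrent 17p loss shared by three patients is derived but was
not printed.  De novo-cohort catalog coordinates are not asserted: several
printed rows are internally inconsistent (bounds vs. size columns).

Cross-study catalog merging clusters same-direction entries by
single-linkage on interval overlap; the consensus location is the cluster
intersection when nonempty, else the flagged member span; group
percentages are `100·count/total` to one decimal.

## Cohort statistics

Group summaries count gains/losses over all patients (zero-CNA patients
stay in the denominator: 104 CNAs over 30 patients give mean 3.47 at two
decimals).  The two-sided Fisher test is computed by full hypergeometric
enumeration — the sum of probabilities of all tables with the observed
margins whose probability does not exceed the observed table's (with a
1e-9 relative guard at ties, the convention of standard implementations);
it matches an independent exact-test oracle on every 2×2 table with both
group sizes ≤ 12 (exhaustively tested).  The chi-square alternative is the
1-df Pearson statistic without continuity correction.  Of note, the
clonality (IG-rearrangement) proportion comparison on the quoted cohort
counts (8/30 vs 2/36) gives an exact p ≈ 0.035; on the table-derived
counts (11/30 vs 5/36) p ≈ 0.044.  Both are reported; neither approaches
the significance level quoted in the source, a discrepancy the pipeline
documents rather than reproduces.

## Karyotype reporting

Calls render in the tables' ISCN-like dialect
(`−7q33q34<135.74–137.48>[0.16]`): sign, chromosome, band span (end band
omitted when equal), Mb positions at 2 decimals in `<>`, linear ratio at 2
decimals in `[]`.  The writer emits a typographic minus and an en dash as
the tables do; the parser also accepts ASCII hyphens and decimal commas.
Karyotype synthesis fuses a patient's adjacent same-direction calls when
the gap is ≤ 2 Mb and mean log2 ratios differ by ≤ 0.2 (defaults chosen so
near-equal neighbors fuse while a nested deep-loss segment — 0.59 next to
0.22 — stays distinct), orders band-level tokens by (chromosome, start)
and appends them to the constitutional prefix; IG/CNV-flagged calls are
excluded.  Translocation/derivative nomenclature is out of scope; input
karyotype structure passes through verbatim.

The packaged cytoband file is an author-constructed **approximate** band
map in UCSC format (it tiles each chromosome and places 21q22.12 so that
the recurrent RUNX1-region deletion names correctly); transcribed cohort
rows carry their printed band text, so fixture-derived reports never
depend on this map.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
per-patient CNA counts are Poisson with the group mean (defaults 3.46
therapy-related, 1.9 de novo), loss:gain odds default 63:41 and 1:1
respectively, event sizes are log-uniform (default 0.1–30 Mb) with a
configurable whole-chromosome probability (monosomy-7-like events), clonal
fractions are uniform on [0.6, 1.0] mirroring a ≥ 60%-blast inclusion
rule, germline CNVs recur with byte-identical breakpoints across carriers,
IG deletions implant inside the configured loci, and therapy-related
samples emit dye-swap pairs with independent noise.  A fixed seed fully
determines the output.

What it does **not** model: GC waves and replication-timing artifacts,
probe-specific response, subclonal mixtures beyond one clonal fraction per
event, and karyotype-level structure (translocations).  Passing recovery
tests therefore demonstrate correctness of the calling chain under the
stated noise model, not performance on raw production arrays.

## Problem sizes used by the test suite

Simulation-backed tests run on scaled-down genomes chosen to exercise the
same statistics quickly: segmentation recovery and null-rate suites use
1 000- and 10 000-probe chromosomes over 200 and 100 seeds; end-to-end
recovery uses 200 single-patient dye-swap cohorts on an 80 Mb two-
chromosome genome at 13 kb probe spacing (~6 100 probes per hybridization);
the generator-calibration test draws 1 000 patients at 250 kb spacing.
The fixture-reproduction and MCR checks run on the full packaged cohort
tables and complete in well under a second.

## Known limitations

* The detection stand-in is not a numerical replica of the original
  proprietary segmenter; only the probe/ratio post-filter is contractual.
* CNV/IG rules depend on the configured region tables; the packaged locus
  extents are approximate stand-ins, clearly marked, and overridable.
* MCR derivation reproduces the published catalog but intentionally emits
  uncurated extra candidates; consumers should treat the output as a
  candidate list, not a curated result.
* The de novo cohort's printed totals and several of its catalog rows are
  mutually inconsistent in the source; the package reports computed values
  and leaves the discrepancies documented rather than reconciled.
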