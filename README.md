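# cnakit

Copy-number analysis of array-CGH leukemia cohorts: aberration calling
from probe-level log2 ratios, rule-based separation of germline copy-number
variants (CNV) and immunoglobulin VDJ deletions from acquired copy-number
abnormalities (CNA), minimal-critical-region (MCR) derivation by
cross-patient interval intersection, cohort comparison statistics, and
ISCN-like karyotype reporting.

It is written for hematology/cytogenomics analysts comparing
therapy-related acute myeloid leukemia (t-AML, secondary to cytotoxic
treatment) against de novo AML (p-AML).  The package ships transcriptions
of a published two-cohort CNA dataset (30 t-AML, 36 p-AML patients on 244K
two-color arrays) and a synthetic-cohort generator with ground truth, so
every stage is exercisable end to end without raw array data.

## The core quantities

**Copy state from linear ratio.**  A segment's linear ratio
r = 2^(mean log2) classifies as high amplification (r ≥ 4), low
amplification (2 ≤ r < 4), gain (1.2 ≤ r < 2), neutral, loss
(0.25 ≤ r ≤ 0.8) or deep loss (r < 0.25).  Ratios are attenuated toward 1
by normal-cell contamination: an event of copy number c in a clonal
fraction f of cells has expected ratio r = 1 + f·(c/2 − 1).

**Detection filter.**  Aberrant segments require ≥ 5 probes and
|log2 ratio| > 0.3; the changepoint search itself is a deterministic
recursive segmentation with a BIC-style penalty plus a short-window
circular-segmentation scan (see `docs/methods.md`).

**Minimal critical region.**  For same-direction CNAs of patients
P₁…Pₖ at a recurrent locus, the MCR is the interval
[max start, min end] of the co-localizing calls — the smallest region
shared by ≥ 2 patients, the natural candidate for a driver gene.  For
example, four patients' 21q22 deletions
⟨34.38–36.12⟩, ⟨35.01–35.60⟩, ⟨35.11–35.15⟩, ⟨34.98–35.29⟩ Mb reduce to
the 0.04 Mb core ⟨35.11–35.15⟩ — the RUNX1 region.

## Worked example

```python
from cnakit import GenomicInterval, intersect_all, derive_mcr_candidates
from cnakit.io import load_fixture

parts = [GenomicInterval.from_mb("21", a, b)
         for a, b in [(34.38, 36.12), (35.01, 35.60), (35.11, 35.15), (34.98, 35.29)]]
core = intersect_all(parts)
print(core.start_mb, core.end_mb, core.size_mb())   # 35.11 35.15 0.04

taml = load_fixture("table4")                        # 30 patient profiles
calls = [c for p in taml for c in p.cna_calls]       # IG-flagged rows excluded
losses = derive_mcr_candidates(calls, "loss")
runx1 = [m for m in losses if m.interval.chrom == "21"][0]
print(sorted(runx1.support), runx1.size_mb)          # ['t-11', 't-29', 't-7', 't-8'] 0.04
```

The cohort-level reproduction runs from the command line:

```
$ cnakit reproduce-paper
taml_n_patients 30
taml_n_cna      104
taml_n_gains    41
taml_n_losses   63
taml_mean_cna_per_case  3.47
taml_patients_no_cna    6
...
taml_mcr_catalog_entries        12
taml_mcr_catalog_matched        12
taml_mcr_min_matched_size_mb    0.03
ig_fisher_p_text_counts 0.03465215371011455
```

Reading: after excluding immunoglobulin-locus deletions, the 30-patient
therapy-related cohort carries 104 acquired CNAs (41 gains, 63 losses,
mean 3.47 per case) and 6 patients have none; the interval-intersection
derivation reproduces all 12 published recurrent regions for this cohort
with identical bounds; and the exact test on the quoted IG-rearrangement
proportions gives p ≈ 0.035.

Other subcommands: `simulate` (synthetic cohorts with truth tables),
`call` (probe table → CNA calls, with optional `--reverse` dye-swap
partner), `annotate` (CNV/IG flags), `mcr`, `stats`, `report` (revised
karyotype strings, e.g. `46,XY,−21q22.1`).

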