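"""End-to-end analysis steps: probes -> segments -> calls -> MCRs -> reports.

Also hosts the fixture reproduction: the packaged cohort tables are run
through the cohort summary, MCR derivation and proportion-test stages, and
the headline numbers are returned as a flat mapping (this is what the
``reproduce-paper`` CLI subcommand prints).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import io as cio
from .classify import (
    ClassificationThresholds,
    CNACall,
    CNVFilterParams,
    annotate_cohort,
    classify_ratio,
)
from .intervals import GenomicInterval, intersect_all, round_mb
from .mcr import MCR, derive_mcr_candidates, match_catalog
from .segmentation import (
    DetectionParams,
    ProbeProfile,
    Segment,
    combine_dye_swap,
    filter_aberrations,
    segment_profile,
)
from .stats import PatientProfile, compare_proportions, summarize_group

__all__ = [
    "call_cna",
    "segments_to_calls",
    "fixture_mcr_candidates",
    "reproduce_paper_report",
]


def segments_to_calls(
    patient: str,
    segments: Sequence[Segment],
    thresholds: ClassificationThresholds | None = None,
) -> list[CNACall]:
    """Classify filtered aberrant segments into CNA calls."""
    thresholds = thresholds or ClassificationThresholds()
    calls = []
    for seg in segments:
        ratio = seg.linear_ratio
        state = classify_ratio(ratio, thresholds)
        if state.direction is None:
            # post-filter segments should not be neutral; skip defensively
            continue
        calls.append(
            CNACall(
                patient=patient,
                interval=seg.interval,
                direction=state.direction,
                linear_ratio=ratio,
                state=state,
                n_probes=seg.n_probes,
            )
        )
    return calls


def call_cna(
    profile: ProbeProfile,
    params: DetectionParams | None = None,
    thresholds: ClassificationThresholds | None = None,
    reverse: ProbeProfile | None = None,
) -> list[CNACall]:
    """Full calling path for one sample (optionally a dye-swap pair)."""
    params = params or DetectionParams()
    if reverse is not None:
        profile, _ = combine_dye_swap(
            profile, reverse, params.dye_swap_discordance_tol
        )
    segments = segment_profile(profile, params)
    kept = filter_aberrations(segments, params)
    return segments_to_calls(profile.sample_id, kept, thresholds)


def _analysable_calls(patients: Sequence[PatientProfile]) -> list[CNACall]:
    return [c for p in patients for c in p.cna_calls]


def fixture_mcr_candidates(group: str = "t-AML", min_support: int = 2) -> list[MCR]:
    """MCR candidates from a packaged cohort table (IG/CNV rows excluded)."""
    table = "table4" if group == "t-AML" else "table5"
    patients = cio.load_fixture(table)
    calls = _analysable_calls(patients)
    return derive_mcr_candidates(calls, "gain", min_support) + derive_mcr_candidates(
        calls, "loss", min_support
    )


def reproduce_paper_report() -> dict[str, float]:
    """Recompute the headline cohort numbers from the packaged tables.

    Returns a flat mapping: per-group CNA counts, gains/losses, means,
    zero-CNA patient counts, the count of published t-AML MCR catalog
    entries matched exactly by the derivation, the minimum matched MCR size,
    and the IG-proportion Fisher p (on the table-derived patient counts and,
    separately, on the narrower counts quoted in the source text).
    """
    taml = cio.load_fixture("table4")
    paml = cio.load_fixture("table5")
    s_t = summarize_group(taml)
    s_p = summarize_group(paml)

    candidates = fixture_mcr_candidates("t-AML")
    catalog = cio.load_fixture("table6")["t-AML"]
    matches = match_catalog(candidates, catalog)
    matched = {entry: cand for entry, cand in matches.items() if cand is not None}
    min_matched_size = min(c.size_mb for c in matched.values()) if matched else math.nan

    report: dict[str, float] = {
        "taml_n_patients": s_t.n_patients,
        "taml_n_cna": s_t.n_cna_total,
        "taml_n_gains": s_t.n_gains,
        "taml_n_losses": s_t.n_losses,
        "taml_mean_cna_per_case": round(s_t.mean_cna_per_case, 2),
        "taml_patients_no_cna": s_t.n_patients_no_cna,
        "taml_patients_ig": s_t.n_patients_ig,
        "paml_n_patients": s_p.n_patients,
        "paml_n_cna": s_p.n_cna_total,
        "paml_n_gains": s_p.n_gains,
        "paml_n_losses": s_p.n_losses,
        "paml_mean_cna_per_case": round(s_p.mean_cna_per_case, 2),
        "paml_patients_no_cna": s_p.n_patients_no_cna,
        "paml_patients_ig": s_p.n_patients_ig,
        "taml_mcr_catalog_entries": len(catalog),
        "taml_mcr_catalog_matched": len(matched),
        "taml_mcr_min_matched_size_mb": min_matched_size,
        "ig_fisher_p_table_counts": compare_proportions(
            s_t.n_patients_ig, s_t.n_patients, s_p.n_patients_ig, s_p.n_patients
        ),
        "ig_fisher_p_text_counts": compare_proportions(8, 30, 2, 36),
    }
    return report


def intersect_patient_calls(
    group: str, chrom: str, direction: str, patients: Sequence[str]
) -> GenomicInterval | None:
    """Intersect the named patients' calls on one chromosome and direction.

    When a patient has several same-direction calls on the chromosome, the
    one overlapping the running intersection is used (the published catalog
    names exactly one contributing call per patient).
    """
    table = "table4" if group == "t-AML" else "table5"
    cohort = cio.load_fixture(table)
    per_patient: dict[str, list[GenomicInterval]] = {}
    for profile in cohort:
        if profile.patient not in patients:
            continue
        for call in profile.cna_calls:
            if call.interval.chrom == chrom and call.direction == direction:
                per_patient.setdefault(profile.patient, []).append(call.interval)
    missing = [p for p in patients if p not in per_patient]
    if missing:
        raise ValueError(f"no {direction} calls on {chrom} for {missing}")
    # order patients by their smallest call, then greedily intersect
    ordered = sorted(patients, key=lambda p: min(i.size_bp() for i in per_patient[p]))
    current: GenomicInterval | None = None
    for patient in ordered:
        options = per_patient[patient]
        if current is None:
            current = min(options, key=lambda i: i.size_bp())
            continue
        overlapping = [i for i in options if i.overlaps(current)]
        if not overlapping:
            return None
        current = intersect_all([current, overlapping[0]])
        if current is None:
            return None
    return current
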