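"""Cytoband lookup, CNA interval notation and revised-karyotype synthesis.

The cohort tables describe each CNA in an ISCN-like dialect:
``−7q33q34<135.74–137.48>[0.16]`` is a loss on 7q33–q34 spanning
135.74–137.48 Mb with linear ratio 0.16.  The karyotype writer renders each
patient's fused, non-IG calls as band-level tokens appended to the
constitutional prefix, e.g. ``46,XY,−21q22.1``.  Sign is written with a
typographic minus and the range with an en dash, as in the tables; the
parser (see :mod:`cnakit.io`) is lenient.
"""

from __future__ import annotations

import bisect
import math
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .classify import CNACall, CopyState
from .intervals import MB, GenomicInterval, round_mb
from .mcr import _chrom_key
from .stats import PatientProfile

__all__ = [
    "CytobandMap",
    "KaryotypeString",
    "band_of",
    "format_cna",
    "fuse_contiguous",
    "synthesize_karyotype",
    "split_band_span",
]

MINUS = "−"
EN_DASH = "–"


@dataclass(frozen=True)
class CytobandMap:
    """Per-chromosome ordered (start, end, band) records, 1-based inclusive.

    Bands must tile each chromosome without gaps or overlaps.
    """

    bands: dict[str, tuple[tuple[int, int, str], ...]]

    def __post_init__(self) -> None:
        for chrom, records in self.bands.items():
            prev_end = 0
            for start, end, _name in records:
                if start != prev_end + 1:
                    raise ValueError(
                        f"cytobands do not tile {chrom}: gap/overlap at {start}"
                    )
                if end < start:
                    raise ValueError(f"empty band on {chrom} at {start}")
                prev_end = end

    def chromosome_length(self, chrom: str) -> int:
        return self.bands[chrom][-1][1]


def band_of(position: int, chrom: str, bands: CytobandMap) -> str:
    """Name of the band containing a 1-based position."""
    try:
        records = bands.bands[chrom]
    except KeyError:
        raise ValueError(f"no bands for chromosome {chrom!r}") from None
    if position < 1 or position > records[-1][1]:
        raise ValueError(f"position {position} outside chromosome {chrom}")
    idx = bisect.bisect_right([r[0] for r in records], position) - 1
    return records[idx][2]


_BAND_BOUNDARY = re.compile(r"(?<=[\dr])[pq]")


def split_band_span(span: str) -> tuple[str, str]:
    """Split a band-span string into (start band, end band).

    ``"q33q34"`` -> ``("q33", "q34")``; a single band spans itself.
    """
    if not span:
        return ("", "")
    m = _BAND_BOUNDARY.search(span, 1)
    if m:
        return span[: m.start()], span[m.start():]
    return span, span


def band_span_of(interval: GenomicInterval, bands: CytobandMap) -> str:
    start_band = band_of(interval.start, interval.chrom, bands)
    end_band = band_of(interval.end, interval.chrom, bands)
    return start_band if start_band == end_band else start_band + end_band


@dataclass(frozen=True)
class KaryotypeString:
    patient: str
    text: str


def _fmt_mb(x: float) -> str:
    return f"{round_mb(x):.2f}"


def format_cna(call: CNACall, bands: CytobandMap | None = None) -> str:
    """Render one call in the tables' dialect.

    ``sign chrom bands <start–end> [ratio]``; the end band is omitted when
    equal to the start band; positions at 2 decimals (Mb), ratio at 2
    decimals.  Neutral calls are not representable.
    """
    if call.state is CopyState.NEUTRAL:
        raise ValueError("cannot format a copy-neutral call")
    sign = "+" if call.direction == "gain" else MINUS
    span = call.band_span
    if span is None:
        if bands is None:
            raise ValueError("no band span on call and no cytoband map given")
        span = band_span_of(call.interval, bands)
    return (
        f"{sign}{call.interval.chrom}{span}"
        f"<{_fmt_mb(call.interval.start_mb)}{EN_DASH}{_fmt_mb(call.interval.end_mb)}>"
        f"[{call.linear_ratio:.2f}]"
    )


def fuse_contiguous(
    calls: Sequence[CNACall],
    gap_tol_mb: float = 2.0,
    ratio_tol_log2: float = 0.2,
) -> list[CNACall]:
    """Fuse a patient's adjacent same-direction calls with similar ratios.

    Neighbors on one chromosome are merged when the inter-call gap is at
    most ``gap_tol_mb`` and their mean log2 ratios differ by at most
    ``ratio_tol_log2`` — a deep-loss segment inside a single-copy loss stays
    distinct.  The merged ratio is the probe-count-weighted geometric mean
    when probe counts are known, else length-weighted.
    """
    patients = {c.patient for c in calls}
    if len(patients) > 1:
        raise ValueError("fuse_contiguous expects calls of a single patient")
    ordered = sorted(
        calls, key=lambda c: (_chrom_key(c.interval.chrom), c.interval.start)
    )
    out: list[CNACall] = []
    for call in ordered:
        if out:
            prev = out[-1]
            same_axis = (
                prev.interval.chrom == call.interval.chrom
                and prev.direction == call.direction
                and prev.flags == call.flags
            )
            gap_bp = call.interval.start - prev.interval.end - 1
            close = gap_bp <= gap_tol_mb * MB
            similar = abs(
                math.log2(prev.linear_ratio) - math.log2(call.linear_ratio)
            ) <= ratio_tol_log2
            if same_axis and close and similar:
                out[-1] = _merge_pair(prev, call)
                continue
        out.append(call)
    return out


def _merge_pair(a: CNACall, b: CNACall) -> CNACall:
    if a.n_probes is not None and b.n_probes is not None:
        wa, wb = a.n_probes, b.n_probes
        n_probes = a.n_probes + b.n_probes
    else:
        wa, wb = a.interval.size_bp(), b.interval.size_bp()
        n_probes = None
    log2 = (wa * math.log2(a.linear_ratio) + wb * math.log2(b.linear_ratio)) / (wa + wb)
    interval = GenomicInterval(a.interval.chrom, a.interval.start, b.interval.end)
    start_a, _ = split_band_span(a.band_span or "")
    _, end_b = split_band_span(b.band_span or "")
    span = None
    if a.band_span is not None and b.band_span is not None:
        span = start_a if start_a == end_b else start_a + end_b
    return replace(
        a,
        interval=interval,
        linear_ratio=round(2.0 ** log2, 2),
        band_span=span,
        n_probes=n_probes,
    )


def synthesize_karyotype(
    patient: PatientProfile,
    bands: CytobandMap | None = None,
    gap_tol_mb: float = 2.0,
    ratio_tol_log2: float = 0.2,
) -> KaryotypeString:
    """Band-level revised karyotype for one patient.

    IG- and CNV-flagged calls are excluded; the remaining calls are fused,
    ordered by (chromosome, start) and appended to the constitutional
    prefix (default ``46,XX``-style prefix must be supplied via the
    profile's karyotype field; structural events in it pass through
    verbatim).
    """
    prefix = patient.karyotype or ""
    fused = fuse_contiguous(patient.cna_calls, gap_tol_mb, ratio_tol_log2)
    tokens = []
    for call in fused:
        sign = "+" if call.direction == "gain" else MINUS
        span = call.band_span
        if span is None:
            if bands is None:
                raise ValueError("no band span on call and no cytoband map given")
            span = band_span_of(call.interval, bands)
        tokens.append(f"{sign}{call.interval.chrom}{span}")
    text = ",".join([prefix] + tokens) if prefix else ",".join(tokens)
    return KaryotypeString(patient=patient.patient, text=text)
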