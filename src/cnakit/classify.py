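"""Copy-state classification and germline-CNV / immunoglobulin-locus flagging.

Linear ratio (2**log2-ratio, tumor/reference) maps to a copy state via fixed
thresholds: gains/losses at 1.2/0.8, low/high amplification at 2/4, deep
(near-homozygous) loss below 0.25.  Acquired copy-number abnormalities (CNA)
are separated from germline copy-number variants (CNV) and from VDJ-type
deletions inside immunoglobulin / T-cell-receptor loci (IG), which mark the
malignant clone rather than a driver lesion; both categories are excluded
from recurrence analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .intervals import GenomicInterval, round_mb

__all__ = [
    "CopyState",
    "ClassificationThresholds",
    "CNACall",
    "CNVFilterParams",
    "NamedLocus",
    "classify_ratio",
    "flag_cnv",
    "flag_ig",
]


class CopyState(enum.Enum):
    HIGH_AMP = "HIGH_AMP"
    LOW_AMP = "LOW_AMP"
    GAIN = "GAIN"
    NEUTRAL = "NEUTRAL"
    LOSS = "LOSS"
    DEEP_LOSS = "DEEP_LOSS"

    @property
    def direction(self) -> str | None:
        if self in (CopyState.HIGH_AMP, CopyState.LOW_AMP, CopyState.GAIN):
            return "gain"
        if self in (CopyState.LOSS, CopyState.DEEP_LOSS):
            return "loss"
        return None


@dataclass(frozen=True)
class ClassificationThresholds:
    """Linear-ratio boundaries; aberrant-side boundaries are inclusive."""

    gain_min: float = 1.2
    loss_max: float = 0.8
    high_amp_min: float = 4.0
    low_amp_min: float = 2.0
    deep_loss_max: float = 0.25

    def __post_init__(self) -> None:
        if not (
            self.deep_loss_max < self.loss_max < 1 < self.gain_min
            < self.low_amp_min < self.high_amp_min
        ):
            raise ValueError("thresholds must be ordered deep_loss < loss < 1 < gain < low_amp < high_amp")


def classify_ratio(
    linear_ratio: float, t: ClassificationThresholds | None = None
) -> CopyState:
    """Map a linear copy ratio to a copy state (total, monotone step function)."""
    t = t or ClassificationThresholds()
    if not linear_ratio > 0:
        raise ValueError(f"linear ratio must be positive, got {linear_ratio}")
    if linear_ratio >= t.high_amp_min:
        return CopyState.HIGH_AMP
    if linear_ratio >= t.low_amp_min:
        return CopyState.LOW_AMP
    if linear_ratio >= t.gain_min:
        return CopyState.GAIN
    if linear_ratio > t.loss_max:
        return CopyState.NEUTRAL
    if linear_ratio >= t.deep_loss_max:
        return CopyState.LOSS
    return CopyState.DEEP_LOSS


@dataclass(frozen=True)
class NamedLocus:
    name: str
    interval: GenomicInterval


@dataclass(frozen=True)
class CNACall:
    """One classified gained/lost interval for one patient."""

    patient: str
    interval: GenomicInterval
    direction: str  # "gain" | "loss"
    linear_ratio: float
    state: CopyState
    flags: frozenset[str] = frozenset()  # subset of {"CNV", "IG", "ARTIFACT"}
    reasons: tuple[str, ...] = ()
    band_span: str | None = None
    n_probes: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain|loss, got {self.direction!r}")
        state_dir = self.state.direction
        if state_dir is not None and state_dir != self.direction:
            raise ValueError(
                f"state {self.state.value} inconsistent with direction {self.direction}"
            )

    @classmethod
    def from_ratio(
        cls,
        patient: str,
        interval: GenomicInterval,
        linear_ratio: float,
        direction: str | None = None,
        thresholds: ClassificationThresholds | None = None,
        **kw,
    ) -> "CNACall":
        """Build a call, deriving state from the ratio.

        Ratios printed at 2 decimals can fall marginally on the neutral side
        of a threshold (e.g. 1.19); when an explicit direction is given it
        decides GAIN/LOSS for such borderline ratios.
        """
        state = classify_ratio(linear_ratio, thresholds)
        if state is CopyState.NEUTRAL:
            if direction is None:
                raise ValueError(f"ratio {linear_ratio} is neutral; no direction given")
            state = CopyState.GAIN if direction == "gain" else CopyState.LOSS
        return cls(
            patient=patient,
            interval=interval,
            direction=direction or state.direction,
            linear_ratio=linear_ratio,
            state=state,
            **kw,
        )

    @property
    def is_analysable(self) -> bool:
        """True when the call enters CNA counting and MCR derivation."""
        return not (self.flags & {"CNV", "IG", "ARTIFACT"})

    def size_mb(self) -> float:
        return self.interval.size_mb()

    def with_flag(self, flag: str, *reasons: str) -> "CNACall":
        return replace(
            self, flags=self.flags | {flag}, reasons=self.reasons + tuple(reasons)
        )


@dataclass(frozen=True)
class CNVFilterParams:
    """Criteria for calling a segment a germline CNV or an IG/TR deletion.

    A call is CNV-flagged when it reciprocally overlaps a known-CNV database
    region (individually sufficient), or when it is small, shares identical
    breakpoints with another patient's same-direction call, and hits a
    configured CNV-prone gene locus (the three criteria must co-occur: shared
    breakpoints alone also arise for true recurrent somatic lesions).
    """

    max_cnv_size_mb: float = 2.0
    breakpoint_identity_tol_mb: float = 0.01  # one 10 kb reporting unit
    min_reciprocal_db_overlap: float = 0.5
    cnv_gene_loci: tuple[NamedLocus, ...] = ()
    ig_loci: tuple[NamedLocus, ...] = ()
    min_ig_containment: float = 0.9

    def __post_init__(self) -> None:
        if self.breakpoint_identity_tol_mb < 0 or self.max_cnv_size_mb < 0:
            raise ValueError("tolerances must be >= 0")
        if not 0 < self.min_reciprocal_db_overlap <= 1:
            raise ValueError("min_reciprocal_db_overlap must be in (0, 1]")


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    shared = a.intersect(b)
    if shared is None:
        return 0.0
    frac = shared.size_bp() / max(a.size_bp(), b.size_bp())
    return frac


def _same_breakpoints(a: GenomicInterval, b: GenomicInterval, tol_mb: float) -> bool:
    tol_bp = round(tol_mb * 1e6)
    return (
        a.chrom == b.chrom
        and abs(a.start - b.start) <= tol_bp
        and abs(a.end - b.end) <= tol_bp
    )


def flag_cnv(
    call: CNACall,
    cohort_calls: Sequence[CNACall],
    cnv_db: Sequence[GenomicInterval],
    params: CNVFilterParams | None = None,
) -> CNACall:
    """Return the call with the CNV flag set when the germline criteria fire.

    Reason codes record which criteria fired: ``db_overlap`` (database
    consultation), ``size`` (< 2 Mb), ``shared_breakpoints`` (identical
    breakpoints in another patient), ``cnv_gene`` (configured locus hit).
    Idempotent and independent of cohort ordering.
    """
    params = params or CNVFilterParams()
    if "CNV" in call.flags:
        return call

    reasons: list[str] = []
    for region in cnv_db:
        if _reciprocal_overlap(call.interval, region) >= params.min_reciprocal_db_overlap:
            reasons.append(f"db_overlap:{region.chrom}:{region.start_mb}-{region.end_mb}")
            break
    if reasons:
        return call.with_flag("CNV", *reasons)

    small = call.size_mb() < params.max_cnv_size_mb
    if not small:
        return call
    sharers = sorted(
        {
            other.patient
            for other in cohort_calls
            if other.patient != call.patient
            and other.direction == call.direction
            and _same_breakpoints(
                call.interval, other.interval, params.breakpoint_identity_tol_mb
            )
        }
    )
    gene_hits = [
        locus.name
        for locus in params.cnv_gene_loci
        if call.interval.overlaps(locus.interval)
    ]
    if sharers and gene_hits:
        return call.with_flag(
            "CNV",
            f"size:{call.size_mb()}Mb",
            "shared_breakpoints:" + ",".join(sharers),
            "cnv_gene:" + ",".join(gene_hits),
        )
    return call


def flag_ig(call: CNACall, params: CNVFilterParams | None = None) -> CNACall:
    """Return the call with the IG flag set for VDJ-type locus deletions.

    Only losses qualify, and the call must lie essentially inside a single
    configured IG/TR locus (containment, not mere overlap: a monosomy 7
    sweeps across the TRG locus but is not a VDJ rearrangement).
    """
    params = params or CNVFilterParams()
    if call.direction != "loss" or "IG" in call.flags:
        return call
    for locus in params.ig_loci:
        shared = call.interval.intersect(locus.interval)
        if shared is None:
            continue
        if shared.size_bp() / call.interval.size_bp() >= params.min_ig_containment:
            return call.with_flag("IG", f"ig_locus:{locus.name}")
    return call


def annotate_cohort(
    calls: Iterable[CNACall],
    cnv_db: Sequence[GenomicInterval],
    params: CNVFilterParams | None = None,
) -> list[CNACall]:
    """Apply IG then CNV flagging to every call of a cohort."""
    params = params or CNVFilterParams()
    calls = list(calls)
    out = []
    for call in calls:
        call = flag_ig(call, params)
        if "IG" not in call.flags:
            call = flag_cnv(call, calls, cnv_db, params)
        out.append(call)
    return out
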