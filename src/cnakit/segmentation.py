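"""Aberration calling from probe-level two-color aCGH log2 ratios.

The detection step is a deterministic recursive binary segmentation: each
chromosome is split at the changepoint maximizing the drop in residual sum
of squares, a split being accepted when the penalized log-likelihood-ratio
gain exceeds a BIC-style penalty (default 10*log(n)); adjacent segments with
near-equal means are then re-merged.  This is a documented stand-in for the
proprietary detection step of the original array platform; the reproducible
part of that pipeline is the published post-filter (>= 5 probes and
|log2 ratio| > 0.3), implemented in :func:`filter_aberrations`.

Therapy-related samples were hybridized as dye-swap pairs; the two
hybridizations are combined probe-wise as ``(forward - reverse)/2`` and
probes whose two measurements disagree are excluded as dye artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, overlap_length

__all__ = [
    "ProbeMeasurement",
    "ProbeProfile",
    "Segment",
    "DetectionParams",
    "combine_dye_swap",
    "segment_profile",
    "filter_aberrations",
]


class ProfileError(ValueError):
    """Invalid probe profile (unsorted, duplicated positions, ...)."""


@dataclass(frozen=True)
class ProbeMeasurement:
    probe_id: str
    interval: GenomicInterval
    log2_ratio: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2_ratio):
            raise ProfileError(f"non-finite log2 ratio for probe {self.probe_id}")


@dataclass(frozen=True)
class ProbeProfile:
    """Ordered per-sample probe measurements. Role: forward|reverse|combined."""

    sample_id: str
    probes: tuple[ProbeMeasurement, ...]
    role: str = "combined"

    def __post_init__(self) -> None:
        if self.role not in ("forward", "reverse", "combined"):
            raise ProfileError(f"bad dye-swap role {self.role!r}")
        seen_chroms: list[str] = []
        prev: ProbeMeasurement | None = None
        for p in self.probes:
            if prev is not None and p.interval.chrom == prev.interval.chrom:
                if p.interval.start == prev.interval.start:
                    raise ProfileError(
                        f"duplicate probe position {p.interval.chrom}:{p.interval.start}"
                        f" ({prev.probe_id}, {p.probe_id})"
                    )
                if p.interval.start < prev.interval.start:
                    raise ProfileError(
                        f"profile not sorted at probe {p.probe_id}"
                    )
            elif p.interval.chrom in seen_chroms:
                raise ProfileError(
                    f"chromosome {p.interval.chrom} not contiguous in profile"
                )
            else:
                seen_chroms.append(p.interval.chrom)
            prev = p

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for p in self.probes:
            if not out or out[-1] != p.interval.chrom:
                out.append(p.interval.chrom)
        return out

    def values(self) -> np.ndarray:
        return np.array([p.log2_ratio for p in self.probes], dtype=float)


@dataclass(frozen=True)
class Segment:
    """A run of probes with common mean log2 ratio."""

    interval: GenomicInterval
    n_probes: int
    mean_log2: float
    probe_span: tuple[int, int]  # [first, last] probe indices within the profile

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("segment must contain at least one probe")

    @property
    def linear_ratio(self) -> float:
        return 2.0 ** self.mean_log2


@dataclass(frozen=True)
class DetectionParams:
    min_probes: int = 5
    min_abs_log2: float = 0.3
    merge_gap_probes: int = 0
    penalty: float | None = None  # None -> 10*log(n) per chromosome
    merge_mean_tol: float = 0.1  # re-merge neighbors closer than this (log2)
    mask_overlap_frac: float = 0.5
    artifact_masks: tuple[GenomicInterval, ...] = ()
    dye_swap_discordance_tol: float = 0.5

    def __post_init__(self) -> None:
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.min_abs_log2 <= 0:
            raise ValueError("min_abs_log2 must be > 0")


def combine_dye_swap(
    forward: ProbeProfile,
    reverse: ProbeProfile,
    discordance_tol: float = 0.5,
) -> tuple[ProbeProfile, list[str]]:
    """Combine a dye-swap pair into one profile.

    Per probe the combined log2 ratio is the mean of the forward value and
    the negated reverse value.  Probes where the two measurements differ by
    more than ``discordance_tol`` (in log2 units, after negating the
    reverse) are excluded; their ids are returned for logging.
    """
    if forward.role != "forward" or reverse.role != "reverse":
        raise ProfileError("profiles must carry forward/reverse roles")
    fkeys = [(p.probe_id, p.interval) for p in forward.probes]
    rkeys = [(p.probe_id, p.interval) for p in reverse.probes]
    if fkeys != rkeys:
        missing = set(k[0] for k in fkeys) ^ set(k[0] for k in rkeys)
        raise ProfileError(
            "dye-swap probe sets differ"
            + (f"; offending probes: {sorted(missing)[:10]}" if missing else "")
        )
    combined: list[ProbeMeasurement] = []
    discordant: list[str] = []
    for f, r in zip(forward.probes, reverse.probes):
        neg_r = -r.log2_ratio
        if abs(f.log2_ratio - neg_r) > discordance_tol:
            discordant.append(f.probe_id)
            continue
        combined.append(
            ProbeMeasurement(f.probe_id, f.interval, 0.5 * (f.log2_ratio + neg_r))
        )
    return (
        ProbeProfile(forward.sample_id, tuple(combined), role="combined"),
        discordant,
    )


def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Best binary split of y: (index k splitting [0:k] / [k:]; RSS drop)."""
    n = y.size
    csum = np.cumsum(y)
    total = csum[-1]
    k = np.arange(1, n)
    left_mean = csum[:-1] / k
    right_mean = (total - csum[:-1]) / (n - k)
    # RSS reduction of a mean split: k*(n-k)/n * (mean_l - mean_r)^2
    gain = k * (n - k) / n * (left_mean - right_mean) ** 2
    best = int(np.argmax(gain))
    return best + 1, float(gain[best])


_MAX_CARVE = 256  # probes; longer events are reachable by plain binary splits


def _best_carve(y: np.ndarray, max_len: int = _MAX_CARVE) -> tuple[int, int, float]:
    """Best interior interval to carve out of y: (start, length, RSS drop).

    A single binary split is nearly blind to a short aberrant run deep
    inside a long segment (its left/right means barely move), so the search
    also scores every interior window up to ``max_len`` probes against its
    complement — the circular-segmentation statistic restricted to short
    windows.
    """
    n = y.size
    csum = np.concatenate(([0.0], np.cumsum(y)))
    total = csum[-1]
    best = (0, 0, 0.0)
    for length in range(2, min(max_len, n - 1) + 1):
        win = csum[length:] - csum[:-length]
        mean_in = win / length
        mean_out = (total - win) / (n - length)
        gain = (mean_in - mean_out) ** 2 * (length * (n - length) / n)
        i = int(np.argmax(gain))
        if gain[i] > best[2]:
            best = (i, length, float(gain[i]))
    return best


def _segment_chromosome(y: np.ndarray, penalty: float) -> list[tuple[int, int]]:
    """Recursive binary segmentation; returns probe-index slices [i, j)."""
    n = y.size
    out: list[tuple[int, int]] = []
    stack = [(0, n)]
    if n > 1:
        # robust noise scale from probe-to-probe differences: immune to the
        # copy-number signal itself (changepoints contribute few diffs)
        mad = float(np.median(np.abs(np.diff(y))))
        sigma = 1.4826 * mad / math.sqrt(2)  # diffs of iid noise have sd sqrt(2)*sigma
    else:
        sigma = 0.0
    # variance floor keeps the statistic defined on zero-noise profiles
    sigma2 = max(sigma * sigma, 1e-12)
    while stack:
        i, j = stack.pop()
        m = j - i
        if m < 2:
            out.append((i, j))
            continue
        seg = y[i:j]
        k, split_gain = _best_split(seg)
        ci, clen, carve_gain = _best_carve(seg)
        # Gaussian LRT gain in units of the noise variance
        if max(split_gain, carve_gain) / sigma2 <= penalty:
            out.append((i, j))
        elif carve_gain > split_gain:
            cuts = sorted({0, ci, ci + clen, m})
            for a, b in zip(cuts[:-1], cuts[1:]):
                stack.append((i + a, i + b))
        else:
            stack.append((i + k, j))
            stack.append((i, i + k))
    out.sort()
    return out


def _merge_slices(
    y: np.ndarray, slices: list[tuple[int, int]], tol: float
) -> list[tuple[int, int]]:
    merged = [slices[0]]
    for i, j in slices[1:]:
        pi, pj = merged[-1]
        if abs(float(np.mean(y[pi:pj])) - float(np.mean(y[i:j]))) < tol:
            merged[-1] = (pi, j)
        else:
            merged.append((i, j))
    return merged


def segment_profile(
    profile: ProbeProfile, params: DetectionParams | None = None
) -> list[Segment]:
    """Partition each chromosome of a profile into constant-mean segments.

    Deterministic for fixed input and parameters.  Segment intervals span
    the first to the last contributing probe.
    """
    params = params or DetectionParams()
    segments: list[Segment] = []
    probes = profile.probes
    values = profile.values()
    # chromosome blocks
    start = 0
    for idx in range(1, len(probes) + 1):
        if idx == len(probes) or probes[idx].interval.chrom != probes[start].interval.chrom:
            y = values[start:idx]
            n = y.size
            penalty = params.penalty if params.penalty is not None else 10.0 * math.log(max(n, 2))
            slices = _segment_chromosome(y, penalty)
            if params.merge_mean_tol > 0 and len(slices) > 1:
                slices = _merge_slices(y, slices, params.merge_mean_tol)
            for i, j in slices:
                first = probes[start + i]
                last = probes[start + j - 1]
                segments.append(
                    Segment(
                        interval=GenomicInterval(
                            first.interval.chrom, first.interval.start, last.interval.end
                        ),
                        n_probes=j - i,
                        mean_log2=float(np.mean(y[i:j])),
                        probe_span=(start + i, start + j - 1),
                    )
                )
            start = idx
    return segments


def filter_aberrations(
    segments: Sequence[Segment], params: DetectionParams | None = None
) -> list[Segment]:
    """Apply the published detection filters to raw segments.

    Keeps segments with at least ``min_probes`` probes and
    ``|mean log2| > min_abs_log2``; removes segments overlapping an artifact
    mask (high-copy repeats, GC-rich or telomeric regions) by at least
    ``mask_overlap_frac`` of their length.
    """
    params = params or DetectionParams()
    kept: list[Segment] = []
    for seg in segments:
        if seg.n_probes < params.min_probes:
            continue
        if abs(seg.mean_log2) <= params.min_abs_log2:
            continue
        masked = False
        for mask in params.artifact_masks:
            shared = seg.interval.intersect(mask)
            if shared is not None and shared.size_bp() >= params.mask_overlap_frac * seg.interval.size_bp():
                masked = True
                break
        if not masked:
            kept.append(seg)
    return kept


def default_telomere_masks(genome, size_bp: int = 100_000) -> tuple[GenomicInterval, ...]:
    """Terminal mask intervals for every chromosome of a genome model."""
    masks = []
    for name in genome.names:
        length = genome.length(name)
        masks.append(GenomicInterval(name, 1, min(size_bp, length)))
        if length > size_bp:
            masks.append(GenomicInterval(name, length - size_bp + 1, length))
    return tuple(masks)
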