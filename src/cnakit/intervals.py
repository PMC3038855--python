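"""Genome model and genomic-interval algebra.

Coordinates are stored 1-based inclusive in base pairs.  The cohort tables
this package works with print positions in Mb at 10 kb resolution, so an
interval printed ``<85.18-167.84>`` maps to base pairs
``[85_180_001, 167_840_000]``; its length is then exactly
``(167.84 - 85.18) Mb``, matching the printed "Size (Mb)" convention.
All reporting rounds half-up to 2 decimals (10 kb).  BED export converts to
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

__all__ = [
    "GenomeModel",
    "GenomicInterval",
    "intersect_all",
    "overlap_length",
    "round_mb",
]

MB = 1_000_000


def round_mb(value: float, ndigits: int = 2) -> float:
    """Round a value in Mb half-up (the tables' convention), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


class IntervalError(ValueError):
    """Contract violation on an interval or genome model."""


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names and lengths (bp).

    The packaged default is the hg18 assembly (see :func:`cnakit.io.load_genome`);
    any two-column ``chrom.sizes``-style file can stand in.
    """

    names: tuple[str, ...]
    lengths: dict[str, int] = field(compare=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise IntervalError("chromosome names must be unique")
        for name in self.names:
            if name not in self.lengths:
                raise IntervalError(f"no length for chromosome {name!r}")
            if self.lengths[name] <= 0:
                raise IntervalError(f"non-positive length for chromosome {name!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeModel":
        pairs = list(pairs)
        return cls(names=tuple(n for n, _ in pairs), lengths={n: int(l) for n, l in pairs})

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise IntervalError(f"unknown chromosome {chrom!r}") from None

    def order(self, chrom: str) -> int:
        """Stable sort key for a chromosome."""
        try:
            return self.names.index(chrom)
        except ValueError:
            raise IntervalError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on one chromosome."""

    chrom: str
    start: int  # bp, 1-based inclusive
    end: int  # bp, inclusive

    def __post_init__(self) -> None:
        if self.start < 1:
            raise IntervalError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise IntervalError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end} (start > end)"
            )

    # -- constructors -------------------------------------------------
    @classmethod
    def from_mb(cls, chrom: str, start_mb: float, end_mb: float) -> "GenomicInterval":
        """Build from the tables' Mb convention ``<start-end>``."""
        start = int(round(start_mb * MB)) + 1
        end = int(round(end_mb * MB))
        return cls(chrom, start, end)

    # -- rendering ----------------------------------------------------
    @property
    def start_mb(self) -> float:
        return round_mb((self.start - 1) / MB)

    @property
    def end_mb(self) -> float:
        return round_mb(self.end / MB)

    def size_bp(self) -> int:
        return self.end - self.start + 1

    def size_mb(self) -> float:
        """Interval length in Mb, half-up at 2 decimals (10 kb resolution)."""
        return round_mb(self.size_bp() / MB)

    def to_bed(self) -> tuple[str, int, int]:
        """0-based half-open triple for BED export."""
        return self.chrom, self.start - 1, self.end

    # -- algebra ------------------------------------------------------
    def validate_on(self, genome: GenomeModel) -> None:
        if self.end > genome.length(self.chrom):
            raise IntervalError(
                f"{self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {genome.length(self.chrom)}"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(self.chrom, max(self.start, other.start), min(self.end, other.end))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> float:
    """Length of the shared span in Mb; 0 for disjoint or different chromosomes."""
    shared = a.intersect(b)
    if shared is None:
        return 0.0
    return shared.size_mb()


def intersect_all(intervals: Sequence[GenomicInterval]) -> GenomicInterval | None:
    """Common intersection of intervals on one chromosome, or None if empty.

    The result is ``[max of starts, min of ends]`` when that span has positive
    length; order of the input does not matter.
    """
    if not intervals:
        raise IntervalError("intersect_all requires a nonempty list")
    chroms = {i.chrom for i in intervals}
    if len(chroms) != 1:
        raise IntervalError(f"intervals span several chromosomes: {sorted(chroms)}")
    start = max(i.start for i in intervals)
    end = min(i.end for i in intervals)
    if start > end:
        return None
    return GenomicInterval(intervals[0].chrom, start, end)
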