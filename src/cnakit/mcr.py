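"""Minimal critical region (MCR) derivation and catalog operations.

An MCR is the smallest genomic interval shared by same-direction CNAs of at
least two patients; it localizes a candidate driver gene.  The derivation is
a seeded-intersection fixpoint: every call seeds a candidate which is
iteratively intersected with overlapping same-direction calls from other
patients, smallest first, until no further call overlaps.  This
reconstruction reproduces the published t-AML catalog bounds exactly from
the per-patient tables, but may emit additional candidates the original
curation omitted (the candidate set is a superset).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .classify import CNACall, CopyState
from .intervals import GenomicInterval, round_mb

__all__ = [
    "MCR",
    "RecurrenceStep",
    "ConsensusMCR",
    "build_recurrence_profile",
    "derive_mcr_candidates",
    "match_catalog",
    "merge_mcr_catalogs",
]

_AMP_STATES = {CopyState.LOW_AMP, CopyState.HIGH_AMP}


def _chrom_key(chrom: str) -> tuple[int, int | str]:
    """Karyotype ordering: numerals numerically, then X, Y."""
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


@dataclass(frozen=True)
class MCR:
    """A recurrent minimal interval and the patients whose CNAs contain it."""

    interval: GenomicInterval
    direction: str
    support: frozenset[str]
    seed_patient: str
    amplified: bool = False

    @property
    def size_mb(self) -> float:
        return self.interval.size_mb()

    def sort_key(self, chrom_order) -> tuple:
        return (chrom_order(self.interval.chrom), self.interval.start, self.interval.end)


@dataclass(frozen=True)
class RecurrenceStep:
    """One constant-depth piece of the cross-patient recurrence pileup."""

    interval: GenomicInterval
    direction: str
    patients: frozenset[str]

    @property
    def depth(self) -> int:
        return len(self.patients)


@dataclass(frozen=True)
class ConsensusMCR:
    """A cross-study consensus region with per-group counts and percentages."""

    interval: GenomicInterval
    direction: str
    exact_consensus: bool  # False when members were disjoint (span reported)
    study_counts: Mapping[str, int]
    group_counts: Mapping[str, int]
    group_percent: Mapping[str, float]


def _analysable(calls: Iterable[CNACall]) -> list[CNACall]:
    return [c for c in calls if c.is_analysable]


def build_recurrence_profile(
    calls: Sequence[CNACall], direction: str
) -> list[RecurrenceStep]:
    """Breakpoint-sweep decomposition of patient coverage, one direction.

    Within each step the supporting patient set is constant; a patient counts
    once however many of their calls cover the step.  Steps with zero depth
    are not emitted, so the emitted steps partition the covered genome.
    """
    calls = [c for c in _analysable(calls) if c.direction == direction]
    steps: list[RecurrenceStep] = []
    by_chrom: dict[str, list[CNACall]] = {}
    for c in calls:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    for chrom in sorted(by_chrom, key=_chrom_key):
        chrom_calls = by_chrom[chrom]
        # breakpoints: interval starts, and ends+1 (1-based inclusive)
        cuts = sorted({c.interval.start for c in chrom_calls} | {c.interval.end + 1 for c in chrom_calls})
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            piece = GenomicInterval(chrom, lo, hi - 1)
            patients = frozenset(
                c.patient for c in chrom_calls if c.interval.overlaps(piece)
            )
            if patients:
                steps.append(RecurrenceStep(piece, direction, patients))
    return steps


def derive_mcr_candidates(
    calls: Sequence[CNACall],
    direction: str,
    min_support: int = 2,
    min_member_overlap: float = 0.5,
) -> list[MCR]:
    """Seeded-intersection fixpoint MCR derivation for one direction.

    For every call (the seed) the candidate interval is intersected with
    each co-localizing same-direction call from other patients, processed in
    ascending (size, patient id) order; calls that no longer co-localize
    with the shrunken interval at their turn are skipped.  One ordered pass
    reaches the fixpoint because intersection only shrinks the interval.

    A call co-localizes when the shared span covers at least
    ``min_member_overlap`` of the smaller of the two intervals: a call that
    merely clips the edge of a recurrent region (e.g. a 30 kb sliver of a
    4 Mb region) does not redefine it.  Set ``min_member_overlap=0`` for
    plain any-overlap intersection.

    Candidates with support below ``min_support`` are dropped; identical
    (interval, direction) candidates are deduplicated keeping the larger
    support (lexicographic patient-set tie-break); a candidate strictly
    containing another candidate with superset-or-equal support is
    discarded.
    """
    pool = [c for c in _analysable(calls) if c.direction == direction]
    order = sorted(pool, key=lambda c: (c.interval.size_bp(), c.patient, c.interval.start))

    raw: list[MCR] = []
    for seed in pool:
        current = seed.interval
        support = {seed.patient}
        contributing = [seed]
        for other in order:
            if other.patient == seed.patient:
                continue
            shared = current.intersect(other.interval)
            if shared is None:
                continue
            if shared.size_bp() < min_member_overlap * min(
                current.size_bp(), other.interval.size_bp()
            ):
                continue
            current = shared
            support.add(other.patient)
            contributing.append(other)
        if len(support) >= min_support:
            amplified = any(c.state in _AMP_STATES for c in contributing)
            raw.append(
                MCR(
                    interval=current,
                    direction=direction,
                    support=frozenset(support),
                    seed_patient=seed.patient,
                    amplified=amplified,
                )
            )

    # deduplicate identical intervals: larger support wins, then lexicographic set
    best: dict[tuple[str, int, int], MCR] = {}
    for cand in raw:
        key = (cand.interval.chrom, cand.interval.start, cand.interval.end)
        prev = best.get(key)
        if prev is None:
            best[key] = cand
            continue
        # larger support wins; equal supports tie-break on seed patient so
        # the result is independent of input order
        rank = (len(cand.support), sorted(cand.support))
        prev_rank = (len(prev.support), sorted(prev.support))
        if rank > prev_rank or (rank == prev_rank and cand.seed_patient < prev.seed_patient):
            best[key] = cand
    candidates = list(best.values())

    # containment pruning: drop X when some Y has Y.interval strictly inside
    # X.interval and Y.support superset-or-equal
    kept: list[MCR] = []
    for x in candidates:
        redundant = any(
            y is not x
            and x.interval.contains(y.interval)
            and x.interval != y.interval
            and y.support >= x.support
            for y in candidates
        )
        if not redundant:
            kept.append(x)

    kept.sort(key=lambda m: (_chrom_key(m.interval.chrom), m.interval.start, m.interval.end))
    return kept


def match_catalog(
    candidates: Sequence[MCR], catalog: Sequence[MCR]
) -> dict[MCR, MCR | None]:
    """Map each catalog entry to a candidate with identical direction and
    identical interval at 10 kb resolution, or None."""
    index = {
        (c.direction, c.interval.chrom, c.interval.start_mb, c.interval.end_mb): c
        for c in candidates
    }
    return {
        entry: index.get(
            (entry.direction, entry.interval.chrom, entry.interval.start_mb, entry.interval.end_mb)
        )
        for entry in catalog
    }


def merge_mcr_catalogs(
    studies: Sequence[tuple[str, Sequence[MCR]]],
    study_group: Mapping[str, str],
    group_totals: Mapping[str, int],
) -> list[ConsensusMCR]:
    """Cluster same-direction entries across studies and compute consensus
    locations with per-group counts and percentages.

    Clustering is single-linkage on interval overlap; the consensus location
    is the intersection of cluster members when nonempty, otherwise the
    member span (flagged).  Percentages are 100*count/group_total to one
    decimal.
    """
    for group, total in group_totals.items():
        if total <= 0:
            raise ValueError(f"group total for {group!r} must be positive")

    entries: list[tuple[str, MCR]] = [
        (study_id, entry) for study_id, members in studies for entry in members
    ]
    n = len(entries)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = entries[i][1], entries[j][1]
            if a.direction == b.direction and a.interval.overlaps(b.interval):
                union(i, j)

    clusters: dict[int, list[tuple[str, MCR]]] = {}
    for i, item in enumerate(entries):
        clusters.setdefault(find(i), []).append(item)

    out: list[ConsensusMCR] = []
    for members in clusters.values():
        intervals = [m.interval for _, m in members]
        start = max(i.start for i in intervals)
        end = min(i.end for i in intervals)
        exact = start <= end
        if exact:
            consensus = GenomicInterval(intervals[0].chrom, start, end)
        else:
            consensus = GenomicInterval(
                intervals[0].chrom,
                min(i.start for i in intervals),
                max(i.end for i in intervals),
            )
        study_counts: dict[str, int] = {}
        group_counts: dict[str, int] = {}
        for study_id, entry in members:
            weight = max(len(entry.support), 1)
            study_counts[study_id] = study_counts.get(study_id, 0) + weight
            group = study_group[study_id]
            group_counts[group] = group_counts.get(group, 0) + weight
        percent = {
            g: round(100.0 * c / group_totals[g], 1)
            for g, c in group_counts.items()
            if g in group_totals
        }
        out.append(
            ConsensusMCR(
                interval=consensus,
                direction=members[0][1].direction,
                exact_consensus=exact,
                study_counts=study_counts,
                group_counts=group_counts,
                group_percent=percent,
            )
        )
    out.sort(key=lambda c: (_chrom_key(c.interval.chrom), c.interval.start, c.direction))
    return out
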