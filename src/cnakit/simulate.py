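"""Synthetic aCGH cohort generation with ground truth.

The generator emulates the statistical structure of two-color 244K aCGH on
acute-leukemia cohorts: per-patient acquired CNA counts are Poisson with the
group mean (defaults 3.46 for therapy-related and 1.9 for de novo cases),
losses outnumber gains in the therapy-related group (63:41), event ratios
are attenuated by the sample's clonal (blast) fraction — sampled uniformly
in [0.6, 1] to mirror the >=60%-blast inclusion rule — germline CNVs recur
with identical breakpoints across carriers, VDJ-type IG deletions occur at
the configured loci, and therapy-related samples are emitted as dye-swap
pairs.  A fixed seed makes the output byte-identical.

The observed linear ratio of an event with ``copy_number`` copies in a
fraction ``f`` of cells against a diploid reference is
``1 + f*(copy_number/2 - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import NamedLocus
from .intervals import MB, GenomeModel, GenomicInterval
from .segmentation import ProbeMeasurement, ProbeProfile

__all__ = [
    "SimConfig",
    "SimEvent",
    "SimTruth",
    "SimulatedCohort",
    "expected_ratio",
    "simulate_cohort",
]


def expected_ratio(copy_number: int, clonal_fraction: float) -> float:
    """Linear tumor/reference ratio of a clonal event in a diploid genome."""
    if copy_number < 0:
        raise ValueError("copy number must be >= 0")
    if not 0 <= clonal_fraction <= 1:
        raise ValueError("clonal fraction must be in [0, 1]")
    return 1.0 + clonal_fraction * (copy_number / 2.0 - 1.0)


@dataclass(frozen=True)
class SimEvent:
    """One implanted event with its ground truth."""

    patient: str
    interval: GenomicInterval
    copy_number: int
    clonal_fraction: float
    category: str  # "CNA" | "CNV" | "IG"

    @property
    def direction(self) -> str:
        return "gain" if self.copy_number > 2 else "loss"

    @property
    def ratio(self) -> float:
        return expected_ratio(self.copy_number, self.clonal_fraction)


@dataclass(frozen=True)
class SimTruth:
    events: tuple[SimEvent, ...]

    def for_patient(self, patient: str) -> list[SimEvent]:
        return [e for e in self.events if e.patient == patient]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient": e.patient,
                    "chrom": e.interval.chrom,
                    "start_mb": e.interval.start_mb,
                    "end_mb": e.interval.end_mb,
                    "direction": e.direction,
                    "copy_number": e.copy_number,
                    "clonal_fraction": round(e.clonal_fraction, 4),
                    "expected_ratio": round(e.ratio, 4),
                    "category": e.category,
                }
                for e in self.events
            ]
        )


@dataclass(frozen=True)
class SimConfig:
    genome: GenomeModel
    probe_spacing_bp: int = 13_000  # ~244K probes genome-wide on hg18
    group_sizes: dict = field(default_factory=lambda: {"t-AML": 30, "p-AML": 36})
    cna_mean: dict = field(default_factory=lambda: {"t-AML": 3.46, "p-AML": 1.9})
    loss_odds: dict = field(default_factory=lambda: {"t-AML": 63 / 41, "p-AML": 1.0})
    ig_probability: dict = field(
        default_factory=lambda: {"t-AML": 8 / 30, "p-AML": 2 / 36}
    )
    size_bounds_mb: tuple[float, float] = (0.1, 30.0)
    whole_chromosome_prob: float = 0.05  # monosomy-7-like events
    amplification_prob: float = 0.03
    clonal_fraction_bounds: tuple[float, float] = (0.6, 1.0)
    noise_sd: float = 0.15
    germline_cnv_panel: tuple[tuple[GenomicInterval, float], ...] = ()
    ig_loci: tuple[NamedLocus, ...] = ()
    dye_swap_groups: tuple[str, ...] = ("t-AML",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe spacing must be positive")
        for prob in list(self.ig_probability.values()) + [
            self.whole_chromosome_prob,
            self.amplification_prob,
        ]:
            if not 0 <= prob <= 1:
                raise ValueError(f"probability {prob} outside [0, 1]")
        lo, hi = self.clonal_fraction_bounds
        if not 0 <= lo <= hi <= 1:
            raise ValueError("clonal fraction bounds must satisfy 0 <= lo <= hi <= 1")


@dataclass(frozen=True)
class SimulatedCohort:
    profiles: dict  # patient -> ProbeProfile or (forward, reverse) pair
    truth: SimTruth
    truth_table: pd.DataFrame


def _probe_grid(genome: GenomeModel, spacing: int) -> list[tuple[str, int]]:
    grid = []
    for chrom in genome.names:
        length = genome.length(chrom)
        pos = spacing // 2
        while pos + 59 <= length:
            grid.append((chrom, pos))
            pos += spacing
    return grid


def _place_event(
    rng: np.random.Generator,
    genome: GenomeModel,
    size_bp: int,
    taken: list[GenomicInterval],
    max_tries: int = 200,
) -> GenomicInterval | None:
    lengths = np.array([genome.length(c) for c in genome.names], dtype=float)
    weights = lengths / lengths.sum()
    for _ in range(max_tries):
        chrom = genome.names[rng.choice(len(genome.names), p=weights)]
        chrom_len = genome.length(chrom)
        if size_bp >= chrom_len:
            continue
        start = int(rng.integers(1, chrom_len - size_bp + 1))
        cand = GenomicInterval(chrom, start, start + size_bp - 1)
        if not any(cand.overlaps(t) for t in taken):
            return cand
    return None


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate probe-level profiles plus ground truth for a cohort.

    Raises when requested events cannot be placed without overlap (genome
    too dense for the configured rates).
    """
    rng = np.random.default_rng(config.seed)
    grid = _probe_grid(config.genome, config.probe_spacing_bp)
    if not grid:
        raise ValueError("probe grid is empty; spacing exceeds chromosome lengths")

    chrom_arr = np.array([c for c, _ in grid])
    pos_arr = np.array([p for _, p in grid], dtype=np.int64)

    events: list[SimEvent] = []
    profiles: dict = {}
    lo_mb, hi_mb = config.size_bounds_mb
    f_lo, f_hi = config.clonal_fraction_bounds

    # decide germline carriers up-front so breakpoints are shared
    carrier_sets: list[tuple[GenomicInterval, float, int]] = list(
        (iv, freq, cn) for (iv, freq), cn in zip(
            config.germline_cnv_panel,
            (1 if i % 2 else 3 for i in range(len(config.germline_cnv_panel))),
        )
    )

    for group, n_patients in config.group_sizes.items():
        mean = config.cna_mean.get(group, 2.0)
        odds = config.loss_odds.get(group, 1.0)
        p_loss = odds / (1.0 + odds)
        ig_p = config.ig_probability.get(group, 0.0)
        dye_swap = group in config.dye_swap_groups
        for i in range(n_patients):
            patient = f"{group}-sim-{i + 1:03d}"
            taken: list[GenomicInterval] = []
            patient_events: list[SimEvent] = []

            # germline CNVs: identical breakpoints for every carrier
            for interval, freq, cn in carrier_sets:
                if rng.random() < freq:
                    if any(interval.overlaps(t) for t in taken):
                        continue
                    taken.append(interval)
                    patient_events.append(
                        SimEvent(patient, interval, cn, 1.0, "CNV")
                    )

            # IG deletion: a focal loss inside one configured locus
            if config.ig_loci and rng.random() < ig_p:
                locus = config.ig_loci[rng.integers(len(config.ig_loci))]
                liv = locus.interval
                min_size = max(2 * config.probe_spacing_bp, 40_000)
                if liv.size_bp() > min_size:
                    size = int(rng.integers(min_size, liv.size_bp()))
                    start = int(rng.integers(liv.start, liv.end - size + 2))
                    interval = GenomicInterval(liv.chrom, start, start + size - 1)
                    if not any(interval.overlaps(t) for t in taken):
                        taken.append(interval)
                        patient_events.append(
                            SimEvent(
                                patient,
                                interval,
                                1,
                                float(rng.uniform(f_lo, f_hi)),
                                "IG",
                            )
                        )

            # acquired CNAs
            n_cna = int(rng.poisson(mean))
            for _ in range(n_cna):
                is_loss = rng.random() < p_loss
                interval = None
                if rng.random() < config.whole_chromosome_prob:
                    # monosomy/trisomy-like event on a randomly chosen free
                    # chromosome; fall back to a sized event if all are taken
                    for ci in rng.permutation(len(config.genome.names)):
                        chrom = config.genome.names[int(ci)]
                        cand = GenomicInterval(chrom, 1, config.genome.length(chrom))
                        if not any(cand.overlaps(t) for t in taken):
                            interval = cand
                            break
                if interval is None:
                    size_mb = float(
                        np.exp(rng.uniform(np.log(lo_mb), np.log(hi_mb)))
                    )
                    size_bp = max(
                        int(size_mb * MB), 2 * config.probe_spacing_bp
                    )
                    interval = _place_event(rng, config.genome, size_bp, taken)
                if interval is None:
                    raise ValueError(
                        "cannot place event without overlap; genome too dense "
                        "for the configured event rates"
                    )
                taken.append(interval)
                if is_loss:
                    cn = 1
                elif rng.random() < config.amplification_prob:
                    cn = int(rng.integers(5, 9))
                else:
                    cn = 3
                patient_events.append(
                    SimEvent(
                        patient,
                        interval,
                        cn,
                        float(rng.uniform(f_lo, f_hi)),
                        "CNA",
                    )
                )

            events.extend(patient_events)

            # probe signal
            signal = np.zeros(len(grid), dtype=float)
            for ev in patient_events:
                mask = (
                    (chrom_arr == ev.interval.chrom)
                    & (pos_arr >= ev.interval.start)
                    & (pos_arr <= ev.interval.end)
                )
                signal[mask] = math.log2(ev.ratio)

            def _profile(values: np.ndarray, role: str) -> ProbeProfile:
                probes = tuple(
                    ProbeMeasurement(
                        probe_id=f"P{k:07d}",
                        interval=GenomicInterval(str(chrom_arr[k]), int(pos_arr[k]), int(pos_arr[k]) + 59),
                        log2_ratio=float(values[k]),
                    )
                    for k in range(len(grid))
                )
                return ProbeProfile(patient, probes, role=role)

            if dye_swap:
                fwd = signal + rng.normal(0.0, config.noise_sd, len(grid))
                rev = -signal + rng.normal(0.0, config.noise_sd, len(grid))
                profiles[patient] = (
                    _profile(fwd, "forward"),
                    _profile(rev, "reverse"),
                )
            else:
                vals = signal + rng.normal(0.0, config.noise_sd, len(grid))
                profiles[patient] = _profile(vals, "combined")

    truth = SimTruth(tuple(events))
    return SimulatedCohort(
        profiles=profiles, truth=truth, truth_table=truth.table()
    )
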