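"""Per-group CNA summaries and two-group proportion tests.

The Fisher test is the two-sided exact test computed by full hypergeometric
enumeration (sum of the probabilities of all 2x2 tables with the observed
margins whose probability does not exceed the observed table's); the
chi-square alternative is the 1-df Pearson statistic without continuity
correction.  Small cohorts make Fisher the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import chi2 as _chi2_dist
from scipy.stats import hypergeom

from .classify import CNACall

__all__ = [
    "PatientProfile",
    "CohortSummary",
    "summarize_group",
    "compare_proportions",
]


@dataclass(frozen=True)
class PatientProfile:
    """One patient's analysable calls plus cohort metadata."""

    patient: str
    group: str
    calls: tuple[CNACall, ...] = ()  # all calls, flags included
    karyotype: str | None = None

    @property
    def cna_calls(self) -> tuple[CNACall, ...]:
        """Calls entering CNA counting (CNV/IG/artifact excluded)."""
        return tuple(c for c in self.calls if c.is_analysable)

    @property
    def ig_rearranged(self) -> bool:
        return any("IG" in c.flags and c.direction == "loss" for c in self.calls)


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_cna_total: int
    n_gains: int
    n_losses: int
    mean_cna_per_case: float
    n_patients_no_cna: int
    n_patients_ig: int

    def __post_init__(self) -> None:
        assert self.n_gains + self.n_losses == self.n_cna_total
        assert self.n_patients_no_cna <= self.n_patients


def summarize_group(patients: Sequence[PatientProfile]) -> CohortSummary:
    """Count gains/losses and per-case means over one cohort group.

    The mean divides by ALL patients of the group (patients without any CNA
    included); it is reported raw, rounding is left to the presentation
    layer.
    """
    n_patients = len(patients)
    gains = sum(1 for p in patients for c in p.cna_calls if c.direction == "gain")
    losses = sum(1 for p in patients for c in p.cna_calls if c.direction == "loss")
    total = gains + losses
    return CohortSummary(
        n_patients=n_patients,
        n_cna_total=total,
        n_gains=gains,
        n_losses=losses,
        mean_cna_per_case=(total / n_patients) if n_patients else 0.0,
        n_patients_no_cna=sum(1 for p in patients if not p.cna_calls),
        n_patients_ig=sum(1 for p in patients if p.ig_rearranged),
    )


def _validate_counts(a: int, n1: int, b: int, n2: int) -> None:
    for name, value in (("a", a), ("n1", n1), ("b", b), ("n2", n2)):
        if value < 0 or value != int(value):
            raise ValueError(f"count {name}={value} must be a nonnegative integer")
    if a > n1 or b > n2:
        raise ValueError(f"successes exceed group sizes: {a}/{n1}, {b}/{n2}")
    if n1 == 0 or n2 == 0:
        raise ValueError("group sizes must be positive")


def _fisher_exact_enumeration(a: int, n1: int, b: int, n2: int) -> float:
    """Two-sided exact p by enumerating the hypergeometric support."""
    successes = a + b
    total = n1 + n2
    dist = hypergeom(total, successes, n1)
    k_min = max(0, successes - n2)
    k_max = min(successes, n1)
    p_obs = dist.pmf(a)
    p = 0.0
    for k in range(k_min, k_max + 1):
        pk = dist.pmf(k)
        # relative tolerance guards against float noise at equal-probability
        # tables (the convention used by standard implementations)
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return min(p, 1.0)


def _chi2_pearson(a: int, n1: int, b: int, n2: int) -> float:
    c, d = n1 - a, n2 - b
    n = n1 + n2
    denom = (a + b) * (c + d) * n1 * n2
    if denom == 0:
        return 1.0
    stat = n * (a * d - b * c) ** 2 / denom
    return float(_chi2_dist.sf(stat, df=1))


def compare_proportions(
    a: int, n1: int, b: int, n2: int, method: str = "fisher"
) -> float:
    """p-value comparing proportions a/n1 vs b/n2 (two-sided).

    ``fisher``: exact enumeration. ``chi2``: Pearson without continuity
    correction, 1 df.
    """
    _validate_counts(a, n1, b, n2)
    if method == "fisher":
        return _fisher_exact_enumeration(a, n1, b, n2)
    if method == "chi2":
        return _chi2_pearson(a, n1, b, n2)
    raise ValueError(f"unknown method {method!r}")
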