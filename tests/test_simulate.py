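"""Synthetic-cohort generator: ratio model, determinism, truth recovery."""

import numpy as np
import pytest

from cnakit.classify import NamedLocus, flag_cnv, flag_ig
from cnakit.intervals import GenomeModel, GenomicInterval
from cnakit.io import default_cnv_filter_params
from cnakit.mcr import derive_mcr_candidates
from cnakit.pipeline import segments_to_calls
from cnakit.segmentation import (
    DetectionParams,
    combine_dye_swap,
    filter_aberrations,
    segment_profile,
)
from cnakit.simulate import SimConfig, expected_ratio, simulate_cohort

SMALL_GENOME = GenomeModel.from_pairs([("1", 40_000_000), ("2", 40_000_000)])


def small_config(**kw):
    base = dict(
        genome=SMALL_GENOME,
        probe_spacing_bp=13_000,
        group_sizes={"t-AML": 1},
        cna_mean={"t-AML": 2.0},
        size_bounds_mb=(0.15, 5.0),
        whole_chromosome_prob=0.0,
        germline_cnv_panel=(),
        ig_loci=(),
        seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestExpectedRatio:
    @pytest.mark.parametrize(
        "cn, f, ratio",
        [
            (2, 0.3, 1.0),
            (2, 1.0, 1.0),
            (1, 0.8, 0.6),
            (0, 0.9, 0.1),
            (3, 1.0, 1.5),
            (4, 0.5, 1.5),
        ],
    )
    def test_mixture_model(self, cn, f, ratio):
        assert expected_ratio(cn, f) == pytest.approx(ratio)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_ratio(-1, 0.5)
        with pytest.raises(ValueError):
            expected_ratio(2, 1.5)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a = simulate_cohort(small_config(seed=42))
        b = simulate_cohort(small_config(seed=42))
        assert a.truth == b.truth
        (fa, ra), = a.profiles.values()
        (fb, rb), = b.profiles.values()
        assert [p.log2_ratio for p in fa.probes] == [p.log2_ratio for p in fb.probes]
        assert [p.log2_ratio for p in ra.probes] == [p.log2_ratio for p in rb.probes]

    def test_different_seed_differs(self):
        a = simulate_cohort(small_config(seed=1))
        b = simulate_cohort(small_config(seed=2))
        (fa, _), = a.profiles.values()
        (fb, _), = b.profiles.values()
        assert [p.log2_ratio for p in fa.probes] != [p.log2_ratio for p in fb.probes]


class TestEventStatistics:
    def test_poisson_mean_within_three_se(self):
        """1000 simulated patients at mean 3.46 give an empirical mean CNA
        count within 3 standard errors of 3.46."""
        cfg = SimConfig(
            genome=GenomeModel.from_pairs([("1", 60_000_000), ("2", 60_000_000)]),
            probe_spacing_bp=250_000,
            group_sizes={"t-AML": 1000},
            cna_mean={"t-AML": 3.46},
            size_bounds_mb=(0.6, 4.0),
            whole_chromosome_prob=0.0,
            germline_cnv_panel=(),
            ig_loci=(),
            dye_swap_groups=(),
            seed=11,
        )
        cohort = simulate_cohort(cfg)
        counts = {}
        for ev in cohort.truth.events:
            if ev.category == "CNA":
                counts[ev.patient] = counts.get(ev.patient, 0) + 1
        per_patient = [counts.get(p, 0) for p in cohort.profiles]
        mean = float(np.mean(per_patient))
        se = np.sqrt(3.46 / 1000)
        assert abs(mean - 3.46) <= 3 * se

    def test_events_cover_at_least_one_probe(self):
        cohort = simulate_cohort(small_config(seed=3, group_sizes={"t-AML": 5}))
        spacing = 13_000
        for ev in cohort.truth.events:
            assert ev.interval.size_bp() >= spacing

    def test_clonal_fractions_respect_blast_selection_rule(self):
        cohort = simulate_cohort(small_config(seed=5, group_sizes={"t-AML": 10}))
        for ev in cohort.truth.events:
            if ev.category != "CNV":
                assert 0.6 <= ev.clonal_fraction <= 1.0


class TestGermlineAndIgImplants:
    PANEL = (
        (GenomicInterval.from_mb("2", 10.0, 10.4), 1.0),
        (GenomicInterval.from_mb("1", 30.0, 30.3), 1.0),
    )
    IG = (NamedLocus("IGH-sim", GenomicInterval.from_mb("1", 20.0, 21.4)),)

    def cohort(self, noise=0.0, seed=9, patients=6):
        return simulate_cohort(
            small_config(
                seed=seed,
                group_sizes={"t-AML": patients},
                germline_cnv_panel=self.PANEL,
                ig_loci=self.IG,
                ig_probability={"t-AML": 1.0},
                noise_sd=noise,
            )
        )

    def test_germline_breakpoints_identical_across_carriers(self):
        cohort = self.cohort()
        for panel_iv, _ in self.PANEL:
            carriers = [
                e.interval
                for e in cohort.truth.events
                if e.category == "CNV" and e.interval.chrom == panel_iv.chrom
            ]
            assert carriers and all(c == panel_iv for c in carriers)

    def test_germline_implants_flagged_cnv_on_noiseless_run(self):
        """With the simulated panel supplied as the database, every germline
        implant call is CNV-flagged after noiseless re-segmentation."""
        cohort = self.cohort(noise=0.0)
        db = [iv for iv, _ in self.PANEL]
        all_calls = []
        for patient, (fwd, rev) in cohort.profiles.items():
            prof, _ = combine_dye_swap(fwd, rev)
            segs = filter_aberrations(segment_profile(prof), DetectionParams())
            all_calls.extend(segments_to_calls(patient, segs))
        flagged = [flag_cnv(c, all_calls, db) for c in all_calls]
        for c in flagged:
            truth_cnv = any(
                e.category == "CNV" and e.interval.overlaps(c.interval)
                and e.patient == c.patient
                for e in cohort.truth.events
            )
            assert ("CNV" in c.flags) == truth_cnv, c

    def test_ig_implants_flagged_and_excluded_from_mcr(self):
        cohort = self.cohort(noise=0.0)
        params = default_cnv_filter_params(ig_loci=self.IG)
        calls = []
        for patient, (fwd, rev) in cohort.profiles.items():
            prof, _ = combine_dye_swap(fwd, rev)
            segs = filter_aberrations(segment_profile(prof), DetectionParams())
            calls.extend(flag_ig(c, params) for c in segments_to_calls(patient, segs))
        ig_truth = [e for e in cohort.truth.events if e.category == "IG"]
        assert ig_truth
        for e in ig_truth:
            matching = [
                c for c in calls if c.patient == e.patient and c.interval.overlaps(e.interval)
            ]
            assert matching and all("IG" in c.flags for c in matching)
        # IG-flagged calls contribute nothing: deriving from the full pool
        # equals deriving from a pool with IG calls physically removed
        with_flags = derive_mcr_candidates(calls, "loss")
        stripped = derive_mcr_candidates(
            [c for c in calls if "IG" not in c.flags], "loss"
        )
        assert with_flags == stripped


class TestEndToEndRecovery:
    def test_zero_noise_recovers_truth_exactly(self):
        cohort = simulate_cohort(small_config(seed=21, noise_sd=0.0))
        (fwd, rev), = cohort.profiles.values()
        prof, _ = combine_dye_swap(fwd, rev)
        segs = filter_aberrations(segment_profile(prof), DetectionParams())
        calls = segments_to_calls(prof.sample_id, segs)
        truth = [e for e in cohort.truth.events if e.category == "CNA"]
        assert len(calls) == len(truth)
        for ev in truth:
            match = [c for c in calls if c.interval.overlaps(ev.interval)]
            assert len(match) == 1
            c = match[0]
            assert c.direction == ev.direction
            # breakpoints exact at probe resolution: recovered span covers
            # exactly the probes inside the implant
            inside = [
                p.interval.start
                for p in prof.probes
                if ev.interval.start <= p.interval.start <= ev.interval.end
            ]
            assert c.interval.start == inside[0]

    def test_noisy_recovery_rate(self):
        """simulate -> combine -> segment -> filter -> classify recovers
        >= 95% of implanted CNAs covering >= 8 probes (clonal fraction >=
        0.6 by construction) at noise sd 0.15 over 200 seeded cohorts, and
        every overlapping call has the correct direction."""
        spacing = 13_000
        total = recovered = 0
        for seed in range(200):
            cohort = simulate_cohort(small_config(seed=seed, noise_sd=0.15))
            (fwd, rev), = cohort.profiles.values()
            prof, _ = combine_dye_swap(fwd, rev)
            segs = filter_aberrations(segment_profile(prof), DetectionParams())
            calls = segments_to_calls(prof.sample_id, segs)
            for ev in cohort.truth.events:
                n_probes = sum(
                    1
                    for p in prof.probes
                    if p.interval.chrom == ev.interval.chrom
                    and ev.interval.start <= p.interval.start <= ev.interval.end
                )
                if n_probes < 8:
                    continue
                total += 1
                overlapping = [c for c in calls if c.interval.overlaps(ev.interval)]
                assert all(c.direction == ev.direction for c in overlapping)
                recovered += any(
                    abs(c.interval.start - ev.interval.start) <= 2.5 * spacing
                    and abs(c.interval.end - ev.interval.end) <= 2.5 * spacing
                    for c in overlapping
                )
        assert total > 200
        assert recovered / total >= 0.95
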