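import numpy as np
import pytest

from cnakit import io as cio
from cnakit.intervals import GenomeModel, GenomicInterval
from cnakit.segmentation import ProbeMeasurement, ProbeProfile

SPACING = 13_000  # bp, ~244K-array density


@pytest.fixture(scope="session")
def genome():
    return cio.load_genome()


@pytest.fixture(scope="session")
def cytobands():
    return cio.load_cytobands()


@pytest.fixture(scope="session")
def taml_cohort():
    return cio.load_fixture("table4")


@pytest.fixture(scope="session")
def paml_cohort():
    return cio.load_fixture("table5")


@pytest.fixture(scope="session")
def mcr_catalog():
    return cio.load_fixture("table6")


@pytest.fixture(scope="session")
def cnv_params():
    return cio.default_cnv_filter_params()


def make_profile(values, chrom="1", spacing=SPACING, sample="s", role="combined"):
    """Probe profile on a regular grid from an array of log2 ratios."""
    probes = tuple(
        ProbeMeasurement(
            f"P{i:06d}",
            GenomicInterval(
                chrom, spacing // 2 + i * spacing, spacing // 2 + i * spacing + 59
            ),
            float(v),
        )
        for i, v in enumerate(np.asarray(values, dtype=float))
    )
    return ProbeProfile(sample, probes, role=role)


@pytest.fixture
def profile_factory():
    return make_profile
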