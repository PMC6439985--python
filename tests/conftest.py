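import numpy as np
import pytest
from hypothesis import settings

from splicealign.examples import toy_gene
from splicealign.simulator import SimConfig, generate_family

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: compact problem scale used by alignment-heavy tests: 2-6 exons of
#: 24-120 nt with 60-200 nt introns keeps genes around 500-1000 nt so
#: whole-family runs (including the quadratic global stage) stay fast
#: while exercising every pipeline path.
COMPACT = SimConfig(
    n_exons_mean=4.0,
    n_exons_range=(2, 6),
    exon_codons_mean=20.0,
    exon_codons_range=(8, 40),
    intron_len_range=(60, 200),
)


@pytest.fixture(scope="session")
def toy():
    """The 63-nt two-isoform toy gene."""
    return toy_gene()


@pytest.fixture(scope="session")
def compact_config():
    return COMPACT


@pytest.fixture(scope="session")
def low_divergence_family():
    rng = np.random.default_rng(7)
    return generate_family("low", COMPACT.scaled(0.04), rng)


@pytest.fixture(scope="session")
def medium_divergence_family():
    rng = np.random.default_rng(19)
    return generate_family("medium", COMPACT.scaled(0.15), rng)
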