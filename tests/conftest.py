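import numpy as np
import pytest

from enhancerscope.intervals import digest
from enhancerscope.simulate import default_config, default_locus, simulate_sequence


@pytest.fixture(scope="session")
def locus():
    return default_locus()


@pytest.fixture(scope="session")
def config():
    """Shared default simulation parameters; treat as read-only."""
    return default_config(seed=0)


@pytest.fixture(scope="session")
def fragmap(locus):
    """DpnII fragment map of one fixed synthetic chromosome realization."""
    seq = simulate_sequence(locus.chrom_length, 123)
    return digest(seq, "GATC", locus.chrom)


@pytest.fixture(scope="session")
def small_fragmap():
    seq = simulate_sequence(200_000, 7)
    return digest(seq, "GATC", "chrT")
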