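import numpy as np
import pytest

from vntrkit import simulate
from vntrkit.locus import synthetic_locus

#: Allele frequencies used throughout (common 2/3/5, rare 1/4).
DEFAULT_FREQS = {1: 0.005, 2: 0.23, 3: 0.34, 4: 0.005, 5: 0.42}


@pytest.fixture(scope="session")
def locus():
    """Synthetic fixture locus: 33-bp unit with the regulatory motif at offset 13.

    400 nt flanks keep simulated haplotype windows small enough for fast
    tests while leaving the k-mer normalization windows fully covered.
    """
    return synthetic_locus(seed=7, flank_len=400)


@pytest.fixture(scope="session")
def read_cfg():
    return simulate.ReadSimConfig(read_length=150, coverage=30.0, error_rate=0.0, flank_len=400)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_individual(h1: int, h2: int, ident: str = "x") -> simulate.Individual:
    return simulate.Individual(id=ident, hap1_copies=h1, hap2_copies=h2)
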