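import numpy as np
import pytest

from gebvpipe import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_population():
    """2 sires x 4 dams x 40 offspring with 20 markers; fully genotyped."""
    ped = simdata.simulate_pedigree(2, 4, 40, seed=11)
    mmap = simdata.default_marker_map(20, 2)
    geno = simdata.simulate_genomes(ped, mmap, 0.5, seed=12)
    return ped, mmap, geno
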