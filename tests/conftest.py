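import numpy as np
import pytest

import riverkin as rk


@pytest.fixture(scope="session")
def uniform_freqs():
    """20 loci with 10 equifrequent alleles — the pedigree-simulation
    reference condition."""
    return [{a + 1: 0.1 for a in range(10)} for _ in range(20)]


@pytest.fixture(scope="session")
def three_deme_data():
    """Deeply diverged 3-deme dataset, 25 individuals per deme, 20 loci."""
    return rk.sim_structured_pops(3, 25, divergence=1.0, theta=2.0,
                                  model=rk.IAM, seed=42)


@pytest.fixture()
def toy_matrix():
    """3 individuals x 1 locus: 100/100, 100/120, 120/120."""
    calls = np.array([[[100, 100]], [[100, 120]], [[120, 120]]])
    return rk.GenotypeMatrix(["i1", "i2", "i3"], ["L1"], calls)
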