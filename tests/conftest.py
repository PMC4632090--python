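import numpy as np
import pytest

from mirpair import synthetic


@pytest.fixture(scope="session")
def small_library():
    """A compact library: 12 known + 3 novel precursors, decoys, repeats."""
    return synthetic.make_precursor_library(12, 3, 3, seed=7)


@pytest.fixture(scope="session")
def quad_design():
    """Two patients with complete pCRC/M/PN/MN quadruples."""
    return synthetic.make_design(2, 1.0, 1.0, seed=0)


@pytest.fixture(scope="session")
def cohort_design():
    """Study-shaped paired design: 38 patients."""
    return synthetic.make_design(38, 0.6, 0.45, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
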