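import numpy as np
import pytest

from hmgdyn import rdc, synthetic


@pytest.fixture(scope="session")
def toy_structure():
    """Default three-helix toy structure (12/10/14 residues, 120/107 deg)."""
    return synthetic.gen_toy_structure()


@pytest.fixture(scope="session")
def toy_ranges():
    return synthetic.toy_segment_ranges((12, 10, 14))


@pytest.fixture(scope="session")
def toy_nh_vectors(toy_structure):
    return rdc.extract_nh_vectors(toy_structure, build_h=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
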