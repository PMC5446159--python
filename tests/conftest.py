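import numpy as np
import pytest

from termddg.rotamers import default_library
from termddg.structure_io import AminoAcidDistribution
from termddg.synthetic import PHI_PSI, build_backbone_chain, random_sequence


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture(scope="session")
def p0_uniform():
    return AminoAcidDistribution.uniform()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def helix30(rng):
    pp = np.tile(PHI_PSI["helix"], (30, 1))
    return build_backbone_chain(pp, random_sequence(30, rng), source_id="helix30_A")


@pytest.fixture
def strand30(rng):
    pp = np.tile(PHI_PSI["strand"], (30, 1))
    return build_backbone_chain(pp, random_sequence(30, rng), source_id="strand30_A")
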