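import numpy as np
import pytest

from kinelastic import enm
from kinelastic.pipeline import STANDIN_LINKER_SEQUENCE, toy_helix_pdb


@pytest.fixture(scope="session")
def helix_structure() -> enm.CaStructure:
    """20-residue ideal-helix Cα trace (synthetic)."""
    return enm.read_ca_structure(toy_helix_pdb(20))


@pytest.fixture(scope="session")
def helix_modes(helix_structure):
    network = enm.build_network(helix_structure, r0=0.5)
    modes = enm.compute_modes(network, helix_structure, 12)
    return helix_structure, network, modes


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def linker_sequence() -> str:
    return STANDIN_LINKER_SEQUENCE
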