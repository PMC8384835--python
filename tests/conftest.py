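import numpy as np
import pytest

from epitopemap import ProteinRecord, assign_pools, tile_protein
from epitopemap.simulate import simulate_protein


@pytest.fixture(scope="session")
def protein_1053():
    """A random 1053-residue antigen (the full-scale library design case)."""
    rng = np.random.default_rng(20210824)
    return simulate_protein(1053, rng)


@pytest.fixture(scope="session")
def library_1053(protein_1053):
    return tile_protein(protein_1053, window=15, stagger=5)


@pytest.fixture(scope="session")
def pools_1053(library_1053):
    return assign_pools(library_1053, pool_size=10)


@pytest.fixture
def tiny_protein():
    return ProteinRecord("tiny", "MKEILVDEARKNSTWYHQCGFPMLVI")
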