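import pytest

from cage_evolve.assembly import assemble_cage, assemble_complex
from cage_evolve.fixtures import (
    LandscapeEvaluator,
    ToyLibrarySpec,
    brute_force_rank,
    make_toy_library,
)
from cage_evolve.precursors import Precursor


@pytest.fixture(scope="session")
def tri_node():
    """Benzene-1,3,5-tricarbaldehyde: the smallest tri-topic node."""
    return Precursor.from_smiles("n1", "O=Cc1cc(C=O)cc(C=O)c1", "node")


@pytest.fixture(scope="session")
def di_linker():
    """Ethylenediamine: the smallest di-topic linker."""
    return Precursor.from_smiles("l1", "NCCN", "linker")


@pytest.fixture(scope="session")
def toy_cage(tri_node, di_linker):
    return assemble_cage(tri_node, di_linker)


@pytest.fixture(scope="session")
def toy_complex(tri_node, di_linker):
    return assemble_complex(tri_node, di_linker)


@pytest.fixture(scope="session")
def toy_library():
    """The 8 x 12 toy library (96 combinations)."""
    return make_toy_library(ToyLibrarySpec(n_nodes=8, n_linkers=12))


@pytest.fixture(scope="session")
def landscape():
    return LandscapeEvaluator()


@pytest.fixture(scope="session")
def oracle_ranking(toy_library, landscape):
    """Exhaustive fitness ranking of all 96 combinations."""
    return brute_force_rank(toy_library, landscape)
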