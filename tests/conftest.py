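import pytest

from enzmech.chemgraph import MolGraph, State
from enzmech.fixtures import amino_acid_library, toy_chemistry


@pytest.fixture(scope="session")
def water():
    return MolGraph.from_atoms(
        [(0, "O", 0), (1, "H", 0), (2, "H", 0)], [(0, 1, "-"), (0, 2, "-")]
    )


@pytest.fixture(scope="session")
def hydroxide():
    return MolGraph.from_atoms([(0, "O", -1), (1, "H", 0)], [(0, 1, "-")])


@pytest.fixture(scope="session")
def ammonia():
    return MolGraph.from_atoms(
        [(0, "N", 0), (1, "H", 0), (2, "H", 0), (3, "H", 0)],
        [(0, 1, "-"), (0, 2, "-"), (0, 3, "-")],
    )


@pytest.fixture(scope="session")
def library():
    return amino_acid_library()


@pytest.fixture(scope="session")
def toy_pt():
    return toy_chemistry("proton_transfer")


@pytest.fixture(scope="session")
def toy_glu():
    return toy_chemistry("glu_tautomerization")


@pytest.fixture(scope="session")
def toy_his_ser():
    return toy_chemistry("his_ser_acyl_transfer")


@pytest.fixture(scope="session")
def toy_fig1():
    return toy_chemistry("fig1_step")


@pytest.fixture(scope="session")
def multistep_toys(toy_pt, toy_glu, toy_his_ser):
    """The toy chemistries with a nontrivial educt->product mechanism."""
    return [toy_pt, toy_glu, toy_his_ser]
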