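"""Shared fixtures: reference molecules, the hydrolase reaction pair, and
seeded toy networks."""

from __future__ import annotations

import pytest

from retrosig.config import RunConfig
from retrosig.fixtures import FixtureSpec, generate_toy_network, generate_group_table
from retrosig.signatures import MolecularGraph

# the two amidohydrolase reactions used throughout as the worked example:
# 6-aminohexanoate-dimer hydrolysis and 4-(gamma-glutamylamino)butanoate
# hydrolysis — same transformation at height 1, diverging context deeper.
AMINOHEXANOATE_DIMER = "NCCCCCC(=O)NCCCCCC(=O)O"
AMINOHEXANOATE = "NCCCCCC(=O)O"
GLUTAMYL_GABA = "NC(CCC(=O)NCCCC(=O)O)C(=O)O"
GABA = "NCCCC(=O)O"
GLUTAMATE = "NC(CCC(=O)O)C(=O)O"
WATER = "O"


@pytest.fixture(scope="session")
def hydrolase_pair():
    """((substrates1, products1), (substrates2, products2)) as (coeff, graph)."""
    g = MolecularGraph.from_smiles
    r1 = (
        [(1, g(AMINOHEXANOATE_DIMER)), (1, g(WATER))],
        [(2, g(AMINOHEXANOATE))],
    )
    r2 = (
        [(1, g(GLUTAMYL_GABA)), (1, g(WATER))],
        [(1, g(GABA)), (1, g(GLUTAMATE))],
    )
    return r1, r2


#: small molecules used for signature property tests (<= 8 heavy atoms for
#: the brute-force canonicalisation oracle)
SMALL_MOLECULES = [
    "C",            # methane
    "CC",           # ethane
    "CCO",          # ethanol
    "CC(=O)O",      # acetic acid
    "NCC(=O)O",     # glycine
    "c1ccccc1",     # benzene
    "CC(C)CO",      # isobutanol
    "C1CC1N",       # cyclopropylamine
    "CC(N)C(=O)O",  # alanine
]


@pytest.fixture(scope="session", params=SMALL_MOLECULES)
def small_molecule(request):
    return MolecularGraph.from_smiles(request.param, name=request.param)


@pytest.fixture(scope="session")
def small_molecules():
    return [MolecularGraph.from_smiles(s, name=s) for s in SMALL_MOLECULES]


@pytest.fixture(scope="session")
def toy_network():
    return generate_toy_network(FixtureSpec(seed=1, n_pairs=1))


@pytest.fixture(scope="session")
def toy_network_two_pairs():
    return generate_toy_network(FixtureSpec(seed=1, n_pairs=2))


@pytest.fixture(scope="session")
def toy_group_table(toy_network):
    return generate_group_table(toy_network, seed=1)


@pytest.fixture()
def config():
    return RunConfig().validate()
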