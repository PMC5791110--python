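import numpy as np
import pytest

from hydrosieve.network import build_network, pack_chains
from hydrosieve.nanopore import assemble_nanopore
from hydrosieve.templates import build_pva_chain, load_template


@pytest.fixture(scope="session")
def dmt():
    return load_template("dimethoate")


@pytest.fixture(scope="session")
def malic():
    return load_template("malic")


@pytest.fixture(scope="session")
def pva5():
    return build_pva_chain(5, tacticity_seed=42)


@pytest.fixture(scope="session")
def malic_pore():
    return assemble_nanopore("malic", 1)


@pytest.fixture(scope="session")
def toy_system():
    """Two 5-mer chains packed close enough to crosslink."""
    return pack_chains(2, 5, box=14.0, min_sep=5.0, seed=3)


@pytest.fixture(scope="session")
def toy_network(toy_system):
    return build_network(toy_system, "malic", 1, seed=1, relax_steps=2)


@pytest.fixture(scope="session")
def full_system():
    """The reference-scale system: 25 chains x 25 monomers in a 70 Å box."""
    return pack_chains(25, 25, box=70.0, min_sep=5.0, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
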