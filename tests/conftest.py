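import numpy as np
import pytest

from hemicoal import SpeciesNetwork, ThreeTaxonNetwork


@pytest.fixture(scope="session")
def base_net():
    """The reference three-taxon parameterization (ILS only)."""
    return ThreeTaxonNetwork(t1=1.0, t2=3.5, tm=0.5, theta=0.002)


@pytest.fixture(scope="session")
def base_species_tree():
    """Species tree matching the reference parameterization, for simulation."""
    return SpeciesNetwork.from_newick("((A:1,B:1):2.5,C:3.5);")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20201221)
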