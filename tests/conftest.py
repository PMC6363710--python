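import numpy as np
import pytest

from picoevo.chronotree import ChronoTree
from picoevo.synthetic_data import simulate_species_tree


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def balanced4():
    """((A,B),(C,D)) with root at 100 Myr, cherries at 40 and 60."""
    return ChronoTree.from_newick("((A:40,B:40):60,(C:60,D:60):40);")


@pytest.fixture(scope="session")
def species8():
    return simulate_species_tree(8, 0.003, 0.001, 1000.0, seed=5)
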