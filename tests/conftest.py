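import numpy as np
import pytest

from phylocontrast import load_table1, parse_newick
from phylocontrast.synthetic_data import SimSpec, simulate_tree


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture()
def three_taxon():
    """The hand-worked example: ((A:1,B:1):1,C:2); with A=4, B=2, C=1."""
    tree = parse_newick("((A:1,B:1):1,C:2);")
    return tree, {"A": 4.0, "B": 2.0, "C": 1.0}


@pytest.fixture(scope="session")
def random_trees():
    """A reusable batch of small random Yule trees (seeded)."""
    rng = np.random.default_rng(20240917)
    trees = []
    for _ in range(50):
        n = int(rng.integers(4, 21))
        trees.append(simulate_tree(SimSpec(n_tips=n, seed=int(rng.integers(2**31)))))
    return trees
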