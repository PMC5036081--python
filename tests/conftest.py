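import numpy as np
import pytest

import cladistron as cl
from cladistron.trees import tree_to_adjacency


@pytest.fixture(scope="session")
def small_sim():
    """8-taxon mixed matrix with known generating tree."""
    tree = cl.simulate_tree(8, seed=1)
    sim = cl.simulate_matrix(
        tree,
        cl.SimConfig(
            n_taxa=8, n_binary=10, n_ordered=5, n_unordered=2,
            rate=0.1, missing_fraction=0.1, polymorphism_fraction=0.03, seed=1,
        ),
    )
    return sim


@pytest.fixture(scope="session")
def study_shaped_sim():
    """Synthetic matrix with the study's dimensions: 34 taxa, 51 characters
    split 28 binary / 19 ordered / 4 unordered."""
    tree = cl.simulate_tree(34, seed=7)
    return cl.simulate_matrix(tree, cl.SimConfig(seed=7))


def random_mixed_matrix(seed, n_taxa=None, rate=None):
    """A small random matrix with all coding features exercised."""
    rng = np.random.default_rng(seed)
    n = n_taxa or int(rng.integers(5, 9))
    tree = cl.simulate_tree(n, seed=seed)
    sim = cl.simulate_matrix(
        tree,
        cl.SimConfig(
            n_taxa=n, n_binary=5, n_ordered=4, n_unordered=2,
            multi_states=int(rng.integers(3, 5)),
            rate=rate if rate is not None else float(rng.uniform(0.05, 0.5)),
            missing_fraction=0.12, polymorphism_fraction=0.05, seed=seed,
        ),
    )
    return sim


def adjacency_of(tree, matrix):
    index = {t: i for i, t in enumerate(matrix.taxa)}
    return tree_to_adjacency(tree, index)
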