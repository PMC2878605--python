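import numpy as np
import pytest

from habitatrates import morphometrics as mo
from habitatrates import synthetic_data as sd
from habitatrates.tree_model import HABITAT_STATES, StochasticMap, Tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def cherry_tree(b1=1.0, b2=1.0):
    """Two-tip star: root with tips A and B."""
    return Tree(parent=[2, 2, -1], blen=[b1, b2, 0.0], labels=["A", "B"])


def three_tip_tree():
    """((A:1,B:1):1,C:2); — balanced, root depth 2."""
    return Tree(parent=[3, 3, 4, 4, -1], blen=[1, 1, 2, 1, 0], labels=["A", "B", "C"])


def single_state_map(tree: Tree, state: str = "terrestrial") -> StochasticMap:
    segs = [
        [(state, float(tree.blen[v]))] if v != tree.root else []
        for v in range(tree.n_nodes)
    ]
    return StochasticMap(tree, segs)


@pytest.fixture
def cherry():
    return cherry_tree()


@pytest.fixture
def balanced3():
    return three_tip_tree()


@pytest.fixture(scope="session")
def small_study():
    """A 40-species synthetic study shared across pipeline tests."""
    cfg = sd.SimConfig(n_tips=40, n_trees=3, maps_per_tree=3, seed=7)
    return sd.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_trait_table(small_study):
    meas = small_study["measurements"]
    pca = mo.pca_correlation(mo.species_means(meas))
    return mo.sampling_variances(meas, pca, 4)


def random_yule_map(n_tips, seed, mk_rate=0.8, states=HABITAT_STATES):
    """Tree + forward-simulated habitat history, for property tests."""
    from habitatrates.habitat_mapping import er_model

    tree = sd.simulate_yule_tree(n_tips, seed=seed)
    smap, data = sd.simulate_mk_history(tree, er_model(mk_rate, states), seed=seed + 1)
    return tree, smap, data
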