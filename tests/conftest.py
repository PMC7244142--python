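import numpy as np
import pytest

from migpipe.simulate import SimulationConfig, simulate_dataset, simulate_species_tree


@pytest.fixture(scope="session")
def small_dataset():
    """Clean amplicon-mode dataset: 8 species, 20 loci, no dropout."""
    cfg = SimulationConfig(
        n_species=8, n_loci=20, read_depth=10, error_rate=0.001, seed=11
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def yule_tree():
    return simulate_species_tree(10, 0.1, 45.0, seed=7)


def true_internal_ages(tree):
    """Preorder-indexed ages of internal nodes (test helper)."""
    return {
        i: n.age
        for i, n in enumerate(tree.preorder_node_iter())
        if not n.is_leaf()
    }
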