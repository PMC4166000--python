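import numpy as np
import pytest

from geneflux.phyletic import PhyleticMatrix
from geneflux.synthetic_data import SimulationConfig, generate_tree, simulate_evolution


@pytest.fixture(scope="session")
def small_sim():
    """A shallow 15-leaf simulation shared by several read-only tests."""
    tree = generate_tree(15, 0.01, seed=7)
    config = SimulationConfig(n_leaves=15, depth=0.01, S_true=800, kappa=9.0 * 800,
                              lam=2.4, mu=9.0, root_families=400, seed=7)
    matrix, truth = simulate_evolution(tree, config)
    return tree, config, matrix, truth


@pytest.fixture
def toy_matrix():
    return PhyleticMatrix(
        ["f1", "f2", "f3"], ["A", "B"], np.array([[1, 0], [2, 1], [0, 3]])
    )
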