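import numpy as np
import pytest

from hippotype import (CVEvaluator, ExpressionMatrix, MarkerSet, SimSpec,
                       simulate_dataset)


@pytest.fixture(scope="session")
def default_sim():
    """One dataset at the simulator's default benchmark settings."""
    return simulate_dataset(SimSpec(seed=1))


@pytest.fixture(scope="session")
def default_evaluator(default_sim):
    return CVEvaluator(default_sim.X_raw, default_sim.true_labels, K=5, seed=0)


@pytest.fixture(scope="session")
def small_sim():
    """A cheap three-type dataset for fast pipeline tests."""
    return simulate_dataset(SimSpec(n_types=3, cells_per_type=60, n_genes=300,
                                    markers_per_type=5, seed=1))


@pytest.fixture
def tiny_matrix():
    """4 genes x 3 cells toy counts with known structure."""
    vals = np.array([
        [2.0, 0.0, 4.0],
        [0.0, 1.0, 0.0],
        [2.0, 0.0, 1.0],
        [0.0, 3.0, 5.0],
    ])
    return ExpressionMatrix(vals, ["g1", "g2", "g3", "g4"], ["c1", "c2", "c3"])


@pytest.fixture
def abc_markers():
    return MarkerSet("toy", {"A": ("g1", "g2"), "B": ("g2", "g3"), "C": ("g2",)})
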