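import numpy as np
import pytest

import rggc


@pytest.fixture
def small_counts() -> rggc.CountMatrix:
    """3 genes x 2 cells toy matrix with explicit ids."""
    return rggc.CountMatrix(
        np.array([[0, 1], [3, 7], [2, 5]]), ["gA", "gB", "gC"], ["c1", "c2"]
    )


@pytest.fixture(scope="session")
def small_sim():
    """A quick, well-separated simulated dataset for pipeline tests."""
    design = rggc.SimDesign(
        n_cells=120,
        n_genes=600,
        n_groups=3,
        group_prob=(1 / 3, 1 / 3, 1 / 3),
        de_prob=(0.3, 0.3, 0.3),
        seed=7,
    )
    return rggc.simulate_counts(design)


@pytest.fixture
def block_W() -> tuple[np.ndarray, np.ndarray]:
    """3-block adjacency (4 nodes per block) with zero inter-block weight."""
    W = np.zeros((12, 12))
    truth = np.repeat([0, 1, 2], 4)
    for b in range(3):
        idx = np.arange(b * 4, (b + 1) * 4)
        W[np.ix_(idx, idx)] = 1.0
    np.fill_diagonal(W, 0.0)
    return W, truth
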