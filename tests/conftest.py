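import numpy as np
import pytest

import cytotrail as ct


@pytest.fixture()
def star3():
    """Small star-topology dataset with ground truth (root + 3 arms)."""
    matrix, truth = ct.simulate_tree_data(
        ct.star3_topology(), n_per_segment=100, n_markers=10, noise_sd=0.1, seed=7
    )
    return matrix, truth


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(30, 4))
    return ct.EventMatrix(
        values,
        ["CD34", "CD45", "CD90", "CD31"],
        [f"c{i}" for i in range(30)],
        ["s0"] * 30,
    )
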