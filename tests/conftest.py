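import numpy as np
import pytest

import neuromass as nm


@pytest.fixture(scope="session")
def small_conn():
    """Seeded 20-region synthetic connectome used across protocol tests."""
    return nm.generate_synthetic_connectome(n_regions=20, density=0.3,
                                            seed=42)


@pytest.fixture(scope="session")
def star_conn():
    """8-node star: centre 0, distinct leaf weights, leaf 1 strongest."""
    n = 8
    W = np.zeros((n, n))
    w = np.array([1.0, 0.55, 0.45, 0.4, 0.35, 0.3, 0.25])
    W[0, 1:] = w
    W[1:, 0] = w
    return nm.ConnectomeMatrix(W, normalized=True)


@pytest.fixture(scope="session")
def random_graph_8():
    """Dense-ish random symmetric 8-node weighted graph."""
    rng = np.random.default_rng(7)
    n = 8
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.55:
                W[i, j] = W[j, i] = rng.random()
    return nm.ConnectomeMatrix(W)
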