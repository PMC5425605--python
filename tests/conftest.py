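import numpy as np
import pytest

from dynfc.community import canonical_labels, louvain


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    """Trigger numba compilation once so timing-sensitive tests are clean."""
    louvain(np.array([[0.0, 1.0], [1.0, 0.0]]), gamma=1.0, seed=0)


def planted_graph(n_nodes=60, n_modules=6, within=0.7, between=0.2,
                  noise=0.02, seed=0):
    """Symmetric nonnegative weight matrix with planted block structure."""
    rng = np.random.default_rng(seed)
    labels = np.sort(np.arange(n_nodes) % n_modules)
    w = np.where(labels[:, None] == labels[None, :], within, between)
    w = w + rng.normal(0.0, noise, (n_nodes, n_nodes))
    w = np.abs(w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w, canonical_labels(labels)


@pytest.fixture
def two_cliques():
    """Two 5-cliques joined by one weak edge; optimum is the 2-way split."""
    w = np.zeros((10, 10))
    w[:5, :5] = 1.0
    w[5:, 5:] = 1.0
    w[4, 5] = w[5, 4] = 0.1
    np.fill_diagonal(w, 0.0)
    return w
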