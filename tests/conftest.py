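import numpy as np
import pytest

import restmodes as rm
from restmodes.communities import modularity_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_clique_matrix():
    """Two 4-node all-positive cliques, no between-clique edges."""
    W = np.zeros((8, 8))
    W[:4, :4] = 1.0
    W[4:, 4:] = 1.0
    np.fill_diagonal(W, 0.0)
    return W


@pytest.fixture(scope="session")
def independent_templates():
    return rm.make_mode_partitions(60, 4, overlap=0.0, seed=101)


def iter_set_partitions(n):
    """All set partitions of n items as restricted-growth label strings."""
    def rec(prefix, maxv):
        if len(prefix) == n:
            yield prefix
            return
        for v in range(maxv + 2):
            yield from rec(prefix + [v], max(maxv, v))
    yield from rec([0], 0)


def exhaustive_max_modularity(W, gamma=1.0):
    """Brute-force maximum of signed modularity over every partition."""
    B = modularity_matrix(W, gamma)
    best = -np.inf
    best_labels = None
    for labels in iter_set_partitions(W.shape[0]):
        lab = np.asarray(labels)
        q = B[lab[:, None] == lab[None, :]].sum()
        if q > best:
            best, best_labels = q, lab
    return best, best_labels


def random_structured_signed_graph(rng, n=None, k=None):
    """Planted-community signed matrix with Gaussian edge noise."""
    n = n if n is not None else int(rng.integers(5, 9))
    k = k if k is not None else int(rng.integers(2, 4))
    labels = rng.integers(0, k, n)
    mu = np.where(labels[:, None] == labels[None, :], 0.8, -0.2)
    W = mu + 0.4 * rng.standard_normal((n, n))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W, labels
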