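import numpy as np
import pytest

from dyncore.community import ModularityParams
from dyncore.netbuild import AdjacencyTensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tensor(rng, n_nodes, n_layers):
    """Random symmetric zero-diagonal tensor with weights in [0, 1]."""
    W = rng.random((n_nodes, n_nodes, n_layers))
    W = (W + W.transpose(1, 0, 2)) / 2
    for l in range(n_layers):
        np.fill_diagonal(W[:, :, l], 0.0)
    return W


@pytest.fixture
def small_tensor(rng):
    return random_tensor(rng, 6, 3)


@pytest.fixture
def dyad_layer():
    """Single layer: unit edges {0-1} and {2-3}."""
    A = np.zeros((4, 4))
    A[0, 1] = A[1, 0] = 1.0
    A[2, 3] = A[3, 2] = 1.0
    return A[:, :, None]


@pytest.fixture
def default_params():
    return ModularityParams(gamma=1.0, omega=1.0)


def brute_force_modularity(W, labels, gamma=1.0, omega=1.0):
    """Independent O((NL)^2) evaluation of the multilayer quality function,
    written as explicit loops over the double sum."""
    N, _, L = W.shape
    total_intra_strength = 0.0
    value = 0.0
    for l in range(L):
        A = W[:, :, l]
        k = A.sum(axis=0)
        two_m = k.sum()
        total_intra_strength += two_m
        for i in range(N):
            for j in range(N):
                if labels[i, l] == labels[j, l]:
                    null = gamma * k[i] * k[j] / two_m if two_m > 0 else 0.0
                    value += A[i, j] - null
    for i in range(N):
        for l in range(L - 1):
            if labels[i, l] == labels[i, l + 1]:
                value += 2.0 * omega  # both (l, l+1) and (l+1, l) orderings
    two_mu = total_intra_strength + 2.0 * omega * N * (L - 1)
    return value / two_mu


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [block + [first]] + partition[i + 1 :]
        yield [[first]] + partition
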