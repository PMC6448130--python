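import numpy as np
import pytest

from hopes.affinity import (
    AffinityConfig,
    knn_local_affinity,
    scaled_exponential_kernel,
    support_mask,
)
from hopes.datatypes import OmicsLayer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_knn_instance(n: int, C: int, seed: int, K: int = 3):
    """Random KNN affinity stacks used by the fusion tests."""
    gen = np.random.default_rng(seed)
    S_list, masks, P_list = [], [], []
    for _ in range(C):
        X = gen.normal(size=(n, 4))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        P = scaled_exponential_kernel(D, AffinityConfig(K=K, mu=0.5))
        S = knn_local_affinity(P, K)
        P_list.append(P)
        S_list.append(S)
        masks.append(support_mask(S))
    return P_list, S_list, masks


@pytest.fixture
def small_layer(rng):
    """20 x 10 complete layer."""
    return OmicsLayer(
        rng.normal(size=(20, 10)),
        [f"s{i}" for i in range(20)],
        [f"f{j}" for j in range(10)],
        name="toy",
    )


def block_similarity(sizes, within=1.0, between=0.0, noise=0.0, seed=0):
    """Planted block-diagonal affinity matrix."""
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    W = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise:
        gen = np.random.default_rng(seed)
        E = gen.normal(0, noise, (n, n))
        W = np.abs(W + (E + E.T) / 2)
    np.fill_diagonal(W, 1.0)
    return W, labels
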