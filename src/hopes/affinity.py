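"""Per-layer sample-similarity construction.

Each omics layer is turned into

* a dense :class:`KernelAffinity` ``P`` via a scaled exponential kernel on
  Euclidean sample distances,
* a KNN-restricted, row-normalised :class:`LocalAffinity` ``S`` that keeps
  only each sample's K strongest neighbours, and
* the binary :class:`SupportMask` of ``S``'s nonzero pattern, which limits
  the path-0 fit of the fused similarity to observed neighbour edges.

The kernel convention follows the similarity-network-fusion family as
implemented in its reference code: entry (i, j) is
``exp(-d(i,j)^2 / (2 * mu * eps_ij))`` where the local bandwidth
``eps_ij`` averages the mean *squared* K-nearest-neighbour distance of i,
the same for j, and ``d(i,j)^2`` itself, so the exponent is a
dimensionless ratio of squared distances and the bandwidth adapts to
local point density.  (Bandwidths measured in raw distance units make the
exponent scale with the absolute distance magnitude, which in
high-dimensional omics data collapses every row of the KNN affinity onto
one or two neighbours.)  ``mu`` is a dimensionless scaling with
recommended range [0.3, 0.8].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import OmicsLayer

__all__ = [
    "AffinityConfig",
    "KernelAffinity",
    "LocalAffinity",
    "SupportMask",
    "pairwise_distances",
    "scaled_exponential_kernel",
    "knn_local_affinity",
    "support_mask",
    "default_k",
    "layer_affinity",
]

_EPS_FLOOR = 1e-12


def default_k(n_samples: int) -> int:
    """Neighbour count scaling with cohort size: max(2, n/10), capped at n-1."""
    return min(max(2, round(n_samples / 10)), n_samples - 1)


@dataclass
class AffinityConfig:
    """Kernel/KNN settings: neighbour count ``K`` and bandwidth scale ``mu``."""

    K: int
    mu: float = 0.5

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


@dataclass
class KernelAffinity:
    """Full (dense) kernel similarity P: symmetric, diagonal 1, entries in (0, 1]."""

    matrix: np.ndarray
    sample_ids: list[str]


@dataclass
class LocalAffinity:
    """KNN-truncated, row-normalised affinity S: each row holds K nonzero
    weights summing to 1 over that sample's nearest neighbours; diagonal 0.

    S is generally *asymmetric* (neighbourhoods are not reciprocal) and no
    stage of the pipeline may assume otherwise.
    """

    matrix: np.ndarray
    sample_ids: list[str]
    K: int


@dataclass
class SupportMask:
    """Binary indicator of a LocalAffinity's nonzero pattern (Omega)."""

    matrix: np.ndarray
    sample_ids: list[str]


def pairwise_distances(layer: OmicsLayer) -> np.ndarray:
    """Euclidean distances between sample rows (symmetric, zero diagonal)."""
    X = layer.values
    if np.isnan(X).any():
        raise ValueError(f"layer {layer.name!r} has missing values; impute first")
    return squareform(pdist(X, metric="euclidean"))


def scaled_exponential_kernel(D: np.ndarray, cfg: AffinityConfig) -> np.ndarray:
    """Density-adaptive Gaussian-type kernel on a distance matrix.

    ``P(i,j) = exp(-D(i,j)^2 / (2 * mu * eps_ij))`` with
    ``eps_ij = (mknn2_i + mknn2_j + D(i,j)^2) / 3`` where ``mknn2_i`` is
    the mean squared distance from i to its K nearest other samples.  A
    vanishing bandwidth (exact duplicate points everywhere) is floored at
    1e-12 with a warning.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if cfg.K >= n:
        raise ValueError(f"K={cfg.K} must be < n={n}")
    D2 = D**2
    # mean squared distance to the K nearest neighbours, excluding self
    D2_sorted = np.sort(D2 + np.diag(np.full(n, np.inf)), axis=1)
    mknn2 = D2_sorted[:, : cfg.K].mean(axis=1)
    eps = (mknn2[:, None] + mknn2[None, :] + D2) / 3.0
    if np.any(eps <= 0):
        warnings.warn(
            "degenerate kernel bandwidth (duplicate points); flooring at 1e-12",
            RuntimeWarning,
            stacklevel=2,
        )
        eps = np.maximum(eps, _EPS_FLOOR)
    P = np.exp(-D2 / (2.0 * cfg.mu * eps))
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 1.0)
    return P


def knn_local_affinity(P: np.ndarray, K: int) -> np.ndarray:
    """Keep the K largest off-diagonal entries per row and row-normalise.

    Ties are broken toward the lower sample index; the diagonal is zeroed
    before truncation so a sample is never its own neighbour.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if not 1 <= K < n:
        raise ValueError(f"K must satisfy 1 <= K < n (got K={K}, n={n})")
    S = P.copy()
    np.fill_diagonal(S, 0.0)
    # stable argsort of -value => ties resolved by ascending index
    order = np.argsort(-S, axis=1, kind="stable")
    keep = np.zeros_like(S, dtype=bool)
    rows = np.repeat(np.arange(n), K)
    keep[rows, order[:, :K].ravel()] = True
    S[~keep] = 0.0
    rowsum = S.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return S / rowsum


def support_mask(S: np.ndarray) -> np.ndarray:
    """Binary mask of the nonzero entries of a local affinity."""
    return (np.asarray(S) != 0).astype(float)


def layer_affinity(
    layer: OmicsLayer, K: int | None = None, mu: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convenience composition: distances -> kernel P -> local S -> mask.

    Returns ``(P, S, mask)`` as plain arrays; ``K`` defaults to
    :func:`default_k` of the cohort size.
    """
    if K is None:
        K = default_k(layer.n_samples)
    D = pairwise_distances(layer)
    P = scaled_exponential_kernel(D, AffinityConfig(K=K, mu=mu))
    S = knn_local_affinity(P, K)
    return P, S, support_mask(S)
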