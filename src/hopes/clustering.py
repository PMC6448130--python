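"""Subtype discovery from a fused similarity matrix.

Spectral clustering on the symmetric normalised Laplacian is the workhorse
(:func:`spectral_cluster`); :func:`consensus_cluster` stabilises it by
Monti-style subsampled co-clustering, and :func:`eigengap_estimate`
suggests a cluster count from the Laplacian spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.linalg
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = [
    "ClusterAssignment",
    "ConsensusMatrix",
    "EigengapResult",
    "spectral_cluster",
    "consensus_cluster",
    "eigengap_estimate",
]


@dataclass
class ClusterAssignment:
    """Integer subtype labels in [0, k) per sample."""

    sample_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sample_ids) != self.labels.size:
            raise ValueError("labels and sample_ids disagree in length")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError(f"labels must lie in [0, {self.k})")

    @property
    def empty_clusters(self) -> list[int]:
        present = set(self.labels.tolist())
        return [c for c in range(self.k) if c not in present]

    def to_series(self):
        import pandas as pd

        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering frequencies across subsampled runs."""

    matrix: np.ndarray
    sample_ids: list[str]
    reps: int
    subsample_fraction: float


class EigengapResult(NamedTuple):
    k: int
    gaps: np.ndarray
    low_confidence: bool


def _sym_laplacian(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    d = W.sum(axis=1)
    d_isqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    L = -W * d_isqrt[:, None] * d_isqrt[None, :]
    np.fill_diagonal(L, 1.0 + np.diag(L))
    return (L + L.T) / 2.0


def spectral_cluster(
    W: np.ndarray,
    k: int,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Normalised spectral clustering of a symmetric nonnegative affinity.

    Uses L_sym = I - D^{-1/2} W D^{-1/2}; the k eigenvectors of smallest
    eigenvalue are row-unit-normalised and clustered by k-means with a
    fixed seed and 20 restarts.  A graph with more connected components
    than k is clustered anyway, with a warning.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n (k={k}, n={n})")
    if np.any(W < -1e-12):
        raise ValueError("affinity must be nonnegative")
    L = _sym_laplacian(W)
    # one extra eigenvalue so a disconnected graph with > k components is
    # detectable
    evals, evecs = scipy.linalg.eigh(L, subset_by_index=(0, min(k, n - 1)))
    n_components = int(np.sum(evals < 1e-10))
    if n_components > k:
        warnings.warn(
            f"graph has more connected components (>= {n_components}) than "
            f"k={k}; clustering anyway",
            RuntimeWarning,
            stacklevel=2,
        )
    U = evecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = U / norms
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    labels = km.fit_predict(U)
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]
    return ClusterAssignment(sample_ids=ids, labels=labels, k=k)


def consensus_cluster(
    W: np.ndarray,
    k: int,
    reps: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    final: str = "hclust",
) -> tuple[ConsensusMatrix, ClusterAssignment]:
    """Monti-style consensus clustering over subsampled spectral runs.

    Each repetition subsamples ``subsample_fraction`` of the cohort without
    replacement, spectral-clusters the induced submatrix, and accumulates
    co-clustering counts; the consensus entry (i, j) is the co-cluster
    count divided by the co-sampling count (0, with a warning, for pairs
    never sampled together).  Final labels come from average-linkage
    hierarchical clustering of 1 - consensus cut at k (``final="hclust"``),
    or from re-running spectral clustering on the consensus matrix
    (``final="spectral"``).
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if final not in ("hclust", "spectral"):
        raise ValueError("final must be 'hclust' or 'spectral'")
    rng = np.random.default_rng(seed)
    m = max(k + 1, int(round(subsample_fraction * n)))
    m = min(m, n)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = spectral_cluster(W[np.ix_(idx, idx)], k, seed=int(rng.integers(2**31)))
        same = sub.labels[:, None] == sub.labels[None, :]
        sampled[np.ix_(idx, idx)] += 1.0
        together[np.ix_(idx, idx)] += same
    never = sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} sample pairs never co-sampled; their "
            "consensus entries are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        consensus = np.where(sampled > 0, together / np.where(sampled > 0, sampled, 1.0), 0.0)
    consensus = (consensus + consensus.T) / 2.0
    np.fill_diagonal(consensus, 1.0)

    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]
    if final == "spectral":
        labels = spectral_cluster(consensus, k, seed=seed).labels
    else:
        dist = 1.0 - consensus
        np.fill_diagonal(dist, 0.0)
        Zl = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(Zl, t=k, criterion="maxclust") - 1
    cm = ConsensusMatrix(
        matrix=consensus, sample_ids=ids, reps=reps, subsample_fraction=subsample_fraction
    )
    return cm, ClusterAssignment(sample_ids=ids, labels=labels, k=k)


def eigengap_estimate(W: np.ndarray, k_max: int = 10) -> EigengapResult:
    """Suggest a cluster count from the largest successive eigenvalue gap
    of L_sym over k = 2..k_max.

    When no gap dominates (e.g. a structureless uniform affinity) the
    smallest candidate k=2 is returned with ``low_confidence=True``.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be < n")
    L = _sym_laplacian(W)
    evals = scipy.linalg.eigh(L, eigvals_only=True, subset_by_index=(0, k_max))
    gaps = np.diff(evals)  # gaps[i] = lambda_{i+2} - lambda_{i+1} (1-based)
    candidates = np.arange(2, k_max + 1)
    cand_gaps = gaps[1:k_max]  # gap following the k-th eigenvalue
    best = int(np.argmax(cand_gaps))
    max_gap = float(cand_gaps[best])
    rest = np.delete(cand_gaps, best)
    dominant = max_gap > 1e-8 and (rest.size == 0 or max_gap > 2.0 * float(np.median(rest)))
    return EigengapResult(k=int(candidates[best]), gaps=cand_gaps, low_confidence=not dominant)
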