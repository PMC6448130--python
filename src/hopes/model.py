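"""Model-style front end.

``HOPES(data).fit()`` and ``SNF(data).fit()`` wrap the functional pipeline
(affinity construction -> fusion) into model / results objects:

>>> sim = simulate_multiomics()
>>> res = HOPES(sim.dataset, alpha=1.0, beta=1.0).fit()
>>> print(res.summary())
>>> subtypes = res.cluster(k=4, seed=0)
>>> ranking = res.select_features("rna", k_clusters=4, n_top=15)

The results object carries the fused similarity, the optimisation trace,
and hooks for clustering, feature back-projection and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .affinity import default_k, layer_affinity
from .clustering import (
    ClusterAssignment,
    ConsensusMatrix,
    EigengapResult,
    consensus_cluster,
    eigengap_estimate,
    spectral_cluster,
)
from .datatypes import MultiOmicsDataset, OmicsLayer
from .feature_selection import FeatureRanking, mcfs_scores
from .fusion import (
    FusedSimilarity,
    FusionConfig,
    FusionDiagnostics,
    hopes_fuse,
    snf_fuse,
)

__all__ = ["HOPES", "SNF", "FusionResults"]


def _as_dataset(data) -> MultiOmicsDataset:
    if isinstance(data, MultiOmicsDataset):
        return data
    if isinstance(data, OmicsLayer):
        return MultiOmicsDataset(layers=[data])
    return MultiOmicsDataset(layers=list(data))


class _FusionModel:
    """Shared plumbing: layers -> (P, S, mask) per layer."""

    def __init__(self, data, K: int | None = None, mu: float = 0.5):
        self.data = _as_dataset(data)
        self.K = K if K is not None else default_k(self.data.n_samples)
        self.mu = mu
        self._affinities: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    @classmethod
    def from_dataframes(cls, frames: dict[str, pd.DataFrame], **kwargs):
        """Build from a mapping of layer name -> samples x features frame."""
        layers = [OmicsLayer.from_dataframe(df, name=name) for name, df in frames.items()]
        return cls(layers, **kwargs)

    @property
    def affinities(self):
        if self._affinities is None:
            self._affinities = [
                layer_affinity(layer, K=self.K, mu=self.mu) for layer in self.data
            ]
        return self._affinities

    @property
    def kernel_list(self) -> list[np.ndarray]:
        return [a[0] for a in self.affinities]

    @property
    def local_affinity_list(self) -> list[np.ndarray]:
        return [a[1] for a in self.affinities]

    @property
    def mask_list(self) -> list[np.ndarray]:
        return [a[2] for a in self.affinities]


class HOPES(_FusionModel):
    """High-order path elucidated similarity model.

    Parameters
    ----------
    data : MultiOmicsDataset or sequence of OmicsLayer
        Layers over one cohort, sample-aligned.
    K, mu : affinity neighbour count and kernel bandwidth scale.
    alpha, beta : weights of the path-1 / path-2 consistency terms.
    Remaining keywords are solver settings (ridge, rho, tol, max_iter, seed).
    """

    def __init__(
        self,
        data,
        K: int | None = None,
        mu: float = 0.5,
        alpha: float = 1.0,
        beta: float = 1.0,
        **solver_kwargs,
    ):
        super().__init__(data, K=K, mu=mu)
        self.config = FusionConfig(alpha=alpha, beta=beta, **solver_kwargs)

    def fit(self) -> "FusionResults":
        fused, diag = hopes_fuse(
            self.local_affinity_list,
            self.mask_list,
            self.config,
            sample_ids=self.data.sample_ids,
        )
        return FusionResults(model=self, fused=fused, diagnostics=diag)


class SNF(_FusionModel):
    """Similarity-network-fusion baseline model (needs >= 2 layers)."""

    def __init__(self, data, K: int | None = None, mu: float = 0.5, iterations: int = 20):
        super().__init__(data, K=K, mu=mu)
        self.iterations = iterations

    def fit(self) -> "FusionResults":
        fused = snf_fuse(
            self.kernel_list,
            self.local_affinity_list,
            iterations=self.iterations,
            sample_ids=self.data.sample_ids,
        )
        return FusionResults(model=self, fused=fused, diagnostics=FusionDiagnostics())


@dataclass
class FusionResults:
    """Fitted fused similarity with clustering / selection / plotting hooks."""

    model: _FusionModel
    fused: FusedSimilarity
    diagnostics: FusionDiagnostics

    @property
    def similarity(self) -> np.ndarray:
        return self.fused.matrix

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fused.sample_ids or [])

    @property
    def converged(self) -> bool:
        return self.fused.converged

    def similarity_frame(self) -> pd.DataFrame:
        ids = self.fused.sample_ids
        return pd.DataFrame(self.fused.matrix, index=ids, columns=ids)

    # -- downstream ---------------------------------------------------------

    def cluster(
        self,
        k: int,
        seed: int = 0,
        consensus: bool = False,
        reps: int = 100,
        subsample_fraction: float = 0.8,
    ) -> ClusterAssignment:
        if consensus:
            _, assign = consensus_cluster(
                self.fused.matrix,
                k,
                reps=reps,
                subsample_fraction=subsample_fraction,
                seed=seed,
                sample_ids=self.fused.sample_ids,
            )
            return assign
        return spectral_cluster(
            self.fused.matrix, k, seed=seed, sample_ids=self.fused.sample_ids
        )

    def consensus(
        self, k: int, seed: int = 0, reps: int = 100, subsample_fraction: float = 0.8
    ) -> tuple[ConsensusMatrix, ClusterAssignment]:
        return consensus_cluster(
            self.fused.matrix,
            k,
            reps=reps,
            subsample_fraction=subsample_fraction,
            seed=seed,
            sample_ids=self.fused.sample_ids,
        )

    def eigengap(self, k_max: int = 10) -> EigengapResult:
        return eigengap_estimate(self.fused.matrix, k_max=k_max)

    def select_features(
        self, layer: str | int, k_clusters: int, n_top: int = 15
    ) -> FeatureRanking:
        return mcfs_scores(
            self.fused.matrix, self.model.data[layer], k_clusters, n_top=n_top
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = []
        title = "Similarity Fusion Results"
        lines.append(title)
        lines.append("=" * 58)
        lines.append(f"{'Method:':<26}{self.fused.method.upper()}")
        lines.append(f"{'No. samples:':<26}{m.data.n_samples}")
        lines.append(f"{'No. layers:':<26}{m.data.n_layers}")
        for layer in m.data:
            lines.append(f"{'  layer ' + layer.name + ':':<26}{layer.n_features} features")
        lines.append(f"{'Affinity K / mu:':<26}{m.K} / {m.mu:g}")
        if isinstance(m, HOPES):
            c = m.config
            lines.append(f"{'alpha / beta:':<26}{c.alpha:g} / {c.beta:g}")
            lines.append(f"{'ridge / rho / tol:':<26}{c.ridge:g} / {c.rho:g} / {c.tol:g}")
            lines.append(f"{'Iterations used:':<26}{self.diagnostics.iterations_used}")
            lines.append(f"{'Converged:':<26}{self.fused.converged}")
            lines.append(f"{'Final energy:':<26}{self.diagnostics.final_energy:.6g}")
            if self.diagnostics.primal_residuals:
                lines.append(
                    f"{'Final primal/dual res:':<26}"
                    f"{self.diagnostics.primal_residuals[-1]:.3g} / "
                    f"{self.diagnostics.dual_residuals[-1]:.3g}"
                )
        elif isinstance(m, SNF):
            lines.append(f"{'SNF iterations:':<26}{m.iterations}")
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- plotting (lazy matplotlib) -----------------------------------------

    def plot_energy(self, ax=None):
        """Objective value per ADMM iteration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fused.energy_trace)
        ax.set_xlabel("iteration")
        ax.set_ylabel("energy")
        ax.set_yscale("log")
        return ax

    def plot_heatmap(self, labels: ClusterAssignment | None = None, ax=None):
        """Fused-similarity heatmap, optionally ordered by cluster labels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        W = self.fused.matrix
        if labels is not None:
            order = np.argsort(labels.labels, kind="stable")
            W = W[np.ix_(order, order)]
        ax.imshow(W, cmap="viridis", interpolation="nearest")
        ax.set_xlabel("samples")
        ax.set_ylabel("samples")
        return ax
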