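"""Synthetic multi-omics benchmark generator.

Emulates the standard planted-cluster design for similarity-fusion
benchmarks: a cohort with a pre-defined cluster structure (default 4
clusters) measured on several layers, where each layer *merges* some true
clusters — i.e. is "indivisible" on its own — so that only integration can
recover the full structure.  Clear-boundary datasets have every sample at
its cluster mean plus noise; fuzzy-boundary datasets additionally
interpolate a fraction of "edge" samples toward an adjacent cluster's
mean.  Additive Gaussian noise of graded standard deviation (low/moderate/
high mapped to sigma = 1, 2, 3) drives the robustness sweep.

Layers can optionally be seeded from real matrices via SVD
(:func:`svd_seed_layers`): cluster-structured sample scores are projected
through the real data's top right-singular vectors and singular-value
scales, preserving its feature-correlation geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .affinity import default_k, layer_affinity
from .clustering import ClusterAssignment, spectral_cluster
from .datatypes import MultiOmicsDataset, OmicsLayer
from .evaluation import nmi
from .fusion import FusionConfig, hopes_fuse, snf_fuse

__all__ = [
    "LayerSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_multiomics",
    "svd_seed_layers",
    "noise_sweep",
    "default_config",
    "fuzzy_config",
]


@dataclass
class LayerSpec:
    """Per-layer design: dimensionality, which true clusters the layer
    cannot distinguish, and the cluster-mean scale.

    ``merge`` lists groups of true-cluster indices that share one mean in
    this layer (e.g. ``[(2, 3)]`` makes clusters 2 and 3 indistinguishable
    here).  ``signal_strength`` is the standard deviation of cluster-mean
    entries, in units of the (unit-variance baseline) noise, so the typical
    per-feature mean separation between two clusters is about
    ``signal_strength * sqrt(2)``.
    """

    n_features: int
    merge: list[tuple[int, ...]] = field(default_factory=list)
    signal_strength: float = 1.5
    name: str | None = None
    n_components: int | None = None  # SVD seeding only


@dataclass
class SimulationConfig:
    n_samples: int = 200
    n_clusters: int = 4
    cluster_proportions: list[float] | None = None
    layer_specs: list[LayerSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    fuzzy_fraction: float = 0.0
    fuzzy_mix: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.layer_specs:
            self.layer_specs = _default_layer_specs()
        if self.cluster_proportions is None:
            self.cluster_proportions = [1.0 / self.n_clusters] * self.n_clusters
        if len(self.cluster_proportions) != self.n_clusters:
            raise ValueError("need one proportion per cluster")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-8:
            raise ValueError("cluster proportions must sum to 1")
        if not 0.0 <= self.fuzzy_fraction < 1.0:
            raise ValueError("fuzzy_fraction must be in [0, 1)")
        for li, spec in enumerate(self.layer_specs):
            if spec.name is None:
                spec.name = f"layer{li + 1}"
            for group in spec.merge:
                for c in group:
                    if not 0 <= c < self.n_clusters:
                        raise ValueError(
                            f"layer {spec.name!r} merge group {group} references "
                            f"unknown cluster {c}"
                        )
        self._warn_inseparable()

    def _warn_inseparable(self) -> None:
        for a in range(self.n_clusters):
            for b in range(a + 1, self.n_clusters):
                separable = any(
                    _effective_map(self.n_clusters, spec.merge)[a]
                    != _effective_map(self.n_clusters, spec.merge)[b]
                    for spec in self.layer_specs
                )
                if not separable:
                    warnings.warn(
                        f"true clusters {a} and {b} are merged in every layer; "
                        "no method can separate them",
                        UserWarning,
                        stacklevel=3,
                    )


def _default_layer_specs() -> list[LayerSpec]:
    """Three layers echoing an RNA / methylation / miRNA dimension
    asymmetry, each merging a different adjacent cluster pair."""
    return [
        LayerSpec(n_features=500, merge=[(0, 1)], name="rna"),
        LayerSpec(n_features=500, merge=[(1, 2)], name="methylation"),
        LayerSpec(n_features=200, merge=[(2, 3)], name="mirna"),
    ]


def default_config(**overrides) -> SimulationConfig:
    """The benchmark's default clear-boundary configuration (4 x 50
    samples, 3 mutually complementary layers)."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def fuzzy_config(**overrides) -> SimulationConfig:
    """Fuzzy-boundary variant: 15% edge samples pulled 0.4 of the way
    toward an adjacent cluster's mean."""
    cfg = SimulationConfig(fuzzy_fraction=0.15, fuzzy_mix=0.4)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimulatedDataset:
    dataset: MultiOmicsDataset
    true_labels: ClusterAssignment
    config: SimulationConfig


def _effective_map(n_clusters: int, merge: list[tuple[int, ...]]) -> np.ndarray:
    """Map true cluster ids to effective (merged) cluster ids, 0-based and
    contiguous, preserving the order of first appearance."""
    parent = list(range(n_clusters))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for group in merge:
        group = list(group)
        for c in group[1:]:
            ra, rb = find(group[0]), find(c)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    roots = [find(c) for c in range(n_clusters)]
    remap: dict[int, int] = {}
    out = np.empty(n_clusters, dtype=int)
    for c, r in enumerate(roots):
        if r not in remap:
            remap[r] = len(remap)
        out[c] = remap[r]
    return out


def _cluster_sizes(cfg: SimulationConfig) -> np.ndarray:
    raw = np.array(cfg.cluster_proportions) * cfg.n_samples
    sizes = np.floor(raw).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    for i in np.argsort(-(raw - sizes))[: cfg.n_samples - sizes.sum()]:
        sizes[i] += 1
    return sizes


def _structure_rng(cfg: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))


def _noise_rng(cfg: SimulationConfig, sigma_idx: int = 0, trial: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, sigma_idx, trial))
    )


def _fuzzy_rng(cfg: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2,)))


def _draw_structure(cfg: SimulationConfig, rng: np.random.Generator = None):
    """Cluster labels and fuzzy-sample assignments.

    Fuzziness uses its own seed stream so that turning ``fuzzy_fraction``
    on or off never shifts the cluster-mean draws.
    """
    sizes = _cluster_sizes(cfg)
    labels = np.repeat(np.arange(cfg.n_clusters), sizes)
    n = cfg.n_samples

    frng = _fuzzy_rng(cfg)
    n_fuzzy = int(np.floor(cfg.fuzzy_fraction * n))
    fuzzy_idx = frng.choice(n, size=n_fuzzy, replace=False) if n_fuzzy else np.empty(0, int)
    fuzzy_partner = np.full(n, -1, dtype=int)
    for i in fuzzy_idx:
        c = labels[i]
        options = [o for o in (c - 1, c + 1) if 0 <= o < cfg.n_clusters]
        fuzzy_partner[i] = int(frng.choice(options))
    return labels, fuzzy_partner


def _layer_scores(
    spec: LayerSpec,
    cfg: SimulationConfig,
    labels: np.ndarray,
    fuzzy_partner: np.ndarray,
    rng: np.random.Generator,
    dim: int,
) -> np.ndarray:
    """Noiseless n x dim score matrix from the layer's effective-cluster
    means, with fuzzy samples interpolated toward their partner cluster."""
    eff = _effective_map(cfg.n_clusters, spec.merge)
    n_eff = eff.max() + 1
    means = rng.normal(0.0, spec.signal_strength, size=(n_eff, dim))
    X = means[eff[labels]]
    for i in np.flatnonzero(fuzzy_partner >= 0):
        own, other = eff[labels[i]], eff[fuzzy_partner[i]]
        X[i] = (1.0 - cfg.fuzzy_mix) * means[own] + cfg.fuzzy_mix * means[other]
    return X


def _assemble(cfg, layers_values, labels) -> SimulatedDataset:
    ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    layers = [
        OmicsLayer(
            vals,
            ids,
            [f"{spec.name}_f{j:05d}" for j in range(vals.shape[1])],
            name=spec.name,
        )
        for spec, vals in zip(cfg.layer_specs, layers_values)
    ]
    truth = ClusterAssignment(sample_ids=ids, labels=labels, k=cfg.n_clusters)
    return SimulatedDataset(dataset=MultiOmicsDataset(layers=layers), true_labels=truth, config=cfg)


def simulate_multiomics(cfg: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a planted-cluster multi-omics dataset.

    Each layer assigns every sample its effective-cluster mean vector
    (true clusters collapsed by the layer's merge groups), interpolates
    fuzzy samples toward an adjacent cluster, and adds i.i.d. Gaussian
    noise of sd ``noise_sd``.  Bit-identical under an identical config.
    """
    cfg = cfg or SimulationConfig()
    srng = _structure_rng(cfg)
    labels, fuzzy_partner = _draw_structure(cfg, srng)
    noiseless = [
        _layer_scores(spec, cfg, labels, fuzzy_partner, srng, spec.n_features)
        for spec in cfg.layer_specs
    ]
    nrng = _noise_rng(cfg)
    values = [
        X + nrng.normal(0.0, cfg.noise_sd, size=X.shape) if cfg.noise_sd > 0 else X.copy()
        for X in noiseless
    ]
    return _assemble(cfg, values, labels)


def svd_seed_layers(
    real_matrices: list[OmicsLayer],
    cfg: SimulationConfig,
) -> SimulatedDataset:
    """Plant the cluster structure inside real layers' feature geometry.

    For each layer, the top right-singular vectors V_r and singular values
    s_r of the corresponding real matrix act as feature loadings and
    scales; cluster-structured sample scores are generated exactly as in
    :func:`simulate_multiomics` (in r dimensions) and the layer is
    ``scores @ (V_r * s_r / sqrt(n_real)).T`` plus Gaussian noise.
    """
    if len(real_matrices) != len(cfg.layer_specs):
        raise ValueError("need one real matrix per layer spec")
    srng = _structure_rng(cfg)
    labels, fuzzy_partner = _draw_structure(cfg, srng)
    noiseless = []
    for spec, real in zip(cfg.layer_specs, real_matrices):
        eff = _effective_map(cfg.n_clusters, spec.merge)
        r = spec.n_components if spec.n_components is not None else int(eff.max() + 1)
        A = real.values - real.values.mean(axis=0)
        rank = np.linalg.matrix_rank(A)
        if rank < r:
            raise ValueError(
                f"real matrix for layer {spec.name!r} has rank {rank} < "
                f"requested {r} components"
            )
        _, sv, Vt = np.linalg.svd(A, full_matrices=False)
        loadings = Vt[:r].T * (sv[:r] / np.sqrt(max(real.n_samples, 1)))
        scores = _layer_scores(spec, cfg, labels, fuzzy_partner, srng, r)
        noiseless.append(scores @ loadings.T)
    nrng = _noise_rng(cfg)
    values = [
        X + nrng.normal(0.0, cfg.noise_sd, size=X.shape) if cfg.noise_sd > 0 else X.copy()
        for X in noiseless
    ]
    out = _assemble(cfg, values, labels)
    # feature ids/dimensions come from the seeding matrices
    for layer, real in zip(out.dataset.layers, real_matrices):
        layer.feature_ids = [str(f) for f in real.feature_ids]
    return out


def _cluster_with_method(
    method: str,
    layer_names: list[str],
    P_list: list[np.ndarray],
    S_list: list[np.ndarray],
    masks: list[np.ndarray],
    k: int,
    seed: int,
    fusion_cfg: FusionConfig,
    snf_iterations: int = 20,
) -> dict[str, np.ndarray]:
    """Cluster labels per reported method name ('single' expands per layer)."""
    out: dict[str, np.ndarray] = {}
    if method == "hopes":
        fused, _ = hopes_fuse(S_list, masks, fusion_cfg)
        out["hopes"] = spectral_cluster(fused.matrix, k, seed=seed).labels
    elif method == "snf":
        fused = snf_fuse(P_list, S_list, iterations=snf_iterations)
        out["snf"] = spectral_cluster(fused.matrix, k, seed=seed).labels
    elif method == "single":
        for name, P in zip(layer_names, P_list):
            out[f"single:{name}"] = spectral_cluster(P, k, seed=seed).labels
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def noise_sweep(
    cfg: SimulationConfig,
    sigmas: list[float],
    trials: int = 20,
    methods: tuple[str, ...] = ("hopes", "snf", "single"),
    fusion_cfg: FusionConfig | None = None,
    K: int | None = None,
    mu: float = 0.5,
    k: int | None = None,
) -> pd.DataFrame:
    """NMI-vs-noise benchmark table.

    The planted structure (labels, cluster means, fuzzy assignments) is
    drawn once from ``cfg.seed``; for every noise level and trial a fresh
    noise realisation is added, each method is run, the result is
    spectral-clustered at the true k, and the NMI against the truth is
    recorded.  Returns a tidy frame with columns method, sigma, trial, nmi.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    fusion_cfg = fusion_cfg or FusionConfig()
    k = k if k is not None else cfg.n_clusters
    srng = _structure_rng(cfg)
    labels, fuzzy_partner = _draw_structure(cfg, srng)
    noiseless = [
        _layer_scores(spec, cfg, labels, fuzzy_partner, srng, spec.n_features)
        for spec in cfg.layer_specs
    ]
    Kn = K if K is not None else default_k(cfg.n_samples)
    layer_names = [spec.name for spec in cfg.layer_specs]
    rows = []
    for si, sigma in enumerate(sigmas):
        for t in range(trials):
            nrng = _noise_rng(cfg, sigma_idx=si, trial=t)
            values = [X + nrng.normal(0.0, sigma, size=X.shape) for X in noiseless]
            sim = _assemble(cfg, values, labels)
            cluster_seed = int(nrng.integers(2**31))
            affinities = [layer_affinity(lay, K=Kn, mu=mu) for lay in sim.dataset.layers]
            P_list = [a[0] for a in affinities]
            S_list = [a[1] for a in affinities]
            mask_list = [a[2] for a in affinities]
            for method in methods:
                results = _cluster_with_method(
                    method, layer_names, P_list, S_list, mask_list,
                    k, cluster_seed, fusion_cfg,
                )
                for name, pred in results.items():
                    rows.append(
                        {
                            "method": name,
                            "sigma": float(sigma),
                            "trial": t,
                            "nmi": nmi(pred, labels),
                        }
                    )
    return pd.DataFrame(rows, columns=["method", "sigma", "trial", "nmi"])
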