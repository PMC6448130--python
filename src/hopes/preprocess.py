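"""Cleaning and normalisation of raw omics matrices.

The standard sequence before affinity construction is

1. :func:`filter_missing` — drop features with too many missing samples,
2. :func:`knn_impute`   — fill remaining gaps from nearest samples,
3. :func:`zscore_normalize` — centre/scale each feature,
4. :func:`top_variable_features` — optionally keep the most variable
   features (e.g. the 1,000 most variable CpG sites of a methylation layer).

All standard deviations here are population standard deviations (divide by
n), one convention used throughout the package.
"""

from __future__ import annotations

import numpy as np

from .datatypes import OmicsLayer

__all__ = [
    "filter_missing",
    "knn_impute",
    "zscore_normalize",
    "top_variable_features",
    "DEFAULT_IMPUTE_NEIGHBORS",
]

#: Default neighbour count for KNN imputation.
DEFAULT_IMPUTE_NEIGHBORS = 10


def filter_missing(layer: OmicsLayer, max_missing_rate: float = 0.2) -> OmicsLayer:
    """Drop features whose missing fraction exceeds ``max_missing_rate``.

    A feature observed in too few samples carries more imputation artefact
    than signal; the conventional cut-off is 20%.  Features with missing
    fraction strictly greater than the threshold are removed; sample order
    is unchanged.
    """
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    frac = np.isnan(layer.values).mean(axis=0)
    keep = np.flatnonzero(frac <= max_missing_rate)
    if keep.size == 0:
        raise ValueError(
            f"layer {layer.name!r}: every feature exceeds missing rate "
            f"{max_missing_rate:g}; nothing left to analyse"
        )
    return layer.select_features(keep)


def _masked_sq_distances(X: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances over mutually observed features,
    rescaled by p / (number of shared features)."""
    n, p = X.shape
    obs = ~np.isnan(X)
    Z = np.where(obs, X, 0.0)
    # sum over shared features of (x-y)^2 = x^2 + y^2 - 2xy restricted to both observed
    sq = Z**2
    xy = Z @ Z.T
    x2 = sq @ obs.T.astype(float)  # sum_j x_ij^2 [j observed in both i and k]
    d2 = x2 + x2.T - 2.0 * xy
    shared = obs.astype(float) @ obs.T.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = d2 * (p / shared)
    d2[shared == 0] = np.inf
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def knn_impute(layer: OmicsLayer, k_neighbors: int = DEFAULT_IMPUTE_NEIGHBORS) -> OmicsLayer:
    """Fill each missing cell with the mean of that feature over the
    nearest samples.

    Distances between samples use only mutually observed features, scaled
    by the number of shared features.  For a missing cell (i, j) the value
    is the mean of feature j over the ``k_neighbors`` samples nearest to i,
    skipping neighbours where feature j is itself missing; if none of those
    neighbours observe feature j, the overall feature mean is used.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    X = layer.values.copy()
    missing = np.isnan(X)
    if not missing.any():
        return layer
    fully_missing = missing.all(axis=0)
    if fully_missing.any():
        bad = [layer.feature_ids[j] for j in np.flatnonzero(fully_missing)[:5]]
        raise ValueError(
            f"layer {layer.name!r}: features with no observed value (run "
            f"filter_missing first): {bad}"
        )
    d2 = _masked_sq_distances(X)
    col_means = np.nanmean(X, axis=0)
    n = X.shape[0]
    order = np.argsort(d2, axis=1, kind="stable")
    for i in np.flatnonzero(missing.any(axis=1)):
        neigh = [s for s in order[i] if s != i][:k_neighbors]
        for j in np.flatnonzero(missing[i]):
            donors = [s for s in neigh if not np.isnan(layer.values[s, j])]
            X[i, j] = np.mean(layer.values[donors, j]) if donors else col_means[j]
    return OmicsLayer(X, layer.sample_ids, layer.feature_ids, layer.name)


def zscore_normalize(layer: OmicsLayer) -> OmicsLayer:
    """Centre each feature to mean 0 and scale to population sd 1.

    Zero-variance features map to all-zero columns rather than dividing
    by zero.
    """
    X = layer.values
    if np.isnan(X).any():
        raise ValueError(f"layer {layer.name!r} still has missing values; impute first")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd
    out = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return OmicsLayer(out, layer.sample_ids, layer.feature_ids, layer.name)


def top_variable_features(layer: OmicsLayer, n_keep: int) -> OmicsLayer:
    """Keep the ``n_keep`` features of largest population standard deviation.

    Ties are broken by original feature order; if ``n_keep >= n_features``
    the layer is returned unchanged.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    p = layer.n_features
    if n_keep >= p:
        return layer
    sd = np.nanstd(layer.values, axis=0)
    # stable sort on -sd keeps original order among ties
    order = np.argsort(-sd, kind="stable")[:n_keep]
    return layer.select_features(sorted(order))
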