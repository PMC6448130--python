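"""Core containers for multi-omics sample x feature data.

An :class:`OmicsLayer` is one omics measurement matrix (expression,
methylation, miRNA, ...) over a common sample cohort; a
:class:`MultiOmicsDataset` is an ordered collection of such layers sharing
the same samples in the same order.  Both are thin, validated wrappers
around :class:`pandas.DataFrame` so that every downstream stage can rely on
aligned sample identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["OmicsLayer", "MultiOmicsDataset"]


def _check_unique(ids: Sequence[str], what: str, layer_name: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} in layer {layer_name!r}: {dupes[:5]}")


@dataclass
class OmicsLayer:
    """One sample x feature omics matrix with aligned identifiers.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_features)
        Real-valued measurements; missing entries are ``nan``.
    sample_ids, feature_ids : sequences of str
        Unique identifiers matching the matrix dimensions.
    name : str
        Free-text layer name (e.g. ``"mrna"``, ``"methylation"``).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    name: str = "layer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.name!r}: values must be 2-D")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"layer {self.name!r}: {n} rows but {len(self.sample_ids)} sample ids"
            )
        if p != len(self.feature_ids):
            raise ValueError(
                f"layer {self.name!r}: {p} columns but {len(self.feature_ids)} feature ids"
            )
        _check_unique(self.sample_ids, "sample ids", self.name)
        _check_unique(self.feature_ids, "feature ids", self.name)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "layer") -> "OmicsLayer":
        """Build a layer from a samples-in-rows DataFrame."""
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(c) for c in df.columns],
            name=name,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def select_features(self, idx: Iterable[int]) -> "OmicsLayer":
        idx = list(idx)
        return OmicsLayer(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[j] for j in idx],
            name=self.name,
        )

    def reorder_samples(self, order: Sequence[int]) -> "OmicsLayer":
        order = list(order)
        return OmicsLayer(
            values=self.values[order, :],
            sample_ids=[self.sample_ids[i] for i in order],
            feature_ids=list(self.feature_ids),
            name=self.name,
        )


@dataclass
class MultiOmicsDataset:
    """Ordered collection of layers over one cohort, samples aligned."""

    layers: list[OmicsLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a MultiOmicsDataset needs at least one layer")
        ref = self.layers[0].sample_ids
        for layer in self.layers[1:]:
            if layer.sample_ids != ref:
                missing = sorted(set(ref) ^ set(layer.sample_ids))
                raise ValueError(
                    f"layer {layer.name!r} sample ids differ from layer "
                    f"{self.layers[0].name!r}; symmetric difference starts with {missing[:5]}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.layers[0].sample_ids)

    @property
    def n_samples(self) -> int:
        return self.layers[0].n_samples

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, key: int | str) -> OmicsLayer:
        if isinstance(key, str):
            for layer in self.layers:
                if layer.name == key:
                    return layer
            raise KeyError(key)
        return self.layers[key]


def align_layers(layers: Sequence[OmicsLayer], intersect: bool = False) -> MultiOmicsDataset:
    """Re-index all layers to the first layer's sample order.

    With ``intersect=False`` (default) any sample-set mismatch is an error;
    with ``intersect=True`` layers are restricted to the common samples, in
    the order they appear in the first layer.
    """
    if not layers:
        raise ValueError("no layers given")
    ref = layers[0].sample_ids
    if intersect:
        common = set(ref)
        for layer in layers[1:]:
            common &= set(layer.sample_ids)
        if not common:
            raise ValueError("no samples shared by all layers")
        ref = [s for s in ref if s in common]
    aligned = []
    for layer in layers:
        lookup = {s: i for i, s in enumerate(layer.sample_ids)}
        missing = [s for s in ref if s not in lookup]
        if missing:
            raise ValueError(
                f"layer {layer.name!r} is missing samples {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        aligned.append(layer.reorder_samples([lookup[s] for s in ref]))
    return MultiOmicsDataset(layers=aligned)
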