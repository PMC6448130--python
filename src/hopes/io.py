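"""Readers/writers for the package's plain-text formats.

Matrix TSV dialect: first row ``sample_id`` followed by feature (or
sample) ids; each subsequent row a sample id then tab-separated numeric
values; UTF-8; missing values as empty cells or ``NA``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .datatypes import OmicsLayer
from .evaluation import SurvivalTable

__all__ = [
    "read_layer_tsv",
    "write_layer_tsv",
    "read_similarity_tsv",
    "write_similarity_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_survival_tsv",
    "read_categories_tsv",
    "write_json",
]

_NA = ["", "NA"]


def read_layer_tsv(path: str | Path, name: str | None = None) -> OmicsLayer:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=_NA, keep_default_na=False)
    return OmicsLayer.from_dataframe(df, name=name or Path(path).stem)


def write_layer_tsv(layer: OmicsLayer, path: str | Path) -> None:
    df = layer.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_similarity_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: similarity matrix rows/columns ids differ")
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def write_similarity_tsv(W: np.ndarray, sample_ids: list[str], path: str | Path) -> None:
    df = pd.DataFrame(W, index=sample_ids, columns=sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_labels_tsv(path: str | Path) -> ClusterAssignment:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "cluster"} <= set(df.columns):
        raise ValueError(f"{path}: labels TSV needs columns sample_id, cluster")
    labels = df["cluster"].to_numpy(dtype=int)
    return ClusterAssignment(
        sample_ids=df["sample_id"].tolist(), labels=labels, k=int(labels.max()) + 1
    )


def write_labels_tsv(assignment: ClusterAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": assignment.sample_ids, "cluster": assignment.labels}
    ).to_csv(path, sep="\t", index=False)


def read_survival_tsv(path: str | Path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "time", "event"} <= set(df.columns):
        raise ValueError(f"{path}: survival TSV needs columns sample_id, time, event")
    return SurvivalTable(
        sample_ids=df["sample_id"].tolist(),
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
    )


def read_categories_tsv(path: str | Path) -> pd.Series:
    """Sample -> category mapping from a two-column TSV (sample_id, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: categories TSV needs columns sample_id, category")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="category")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
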