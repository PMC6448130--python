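"""End-to-end pipeline: preprocess -> affinity -> fuse -> cluster ->
evaluate -> select features, driven by a validated YAML config.

Outputs (fused matrix, labels, metrics, per-layer feature rankings) are
written to an output directory together with a manifest recording the
config hash, package version and seed, so a run can be reproduced from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__, io
from .datatypes import align_layers
from .evaluation import chi_square_association, logrank_test, matched_accuracy, nmi
from .feature_selection import select_top_features
from .model import HOPES, SNF
from .preprocess import filter_missing, knn_impute, top_variable_features, zscore_normalize

logger = logging.getLogger("hopes")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class PreprocessConfig(BaseModel):
    max_missing_rate: float = Field(0.2, ge=0.0, le=1.0)
    impute_neighbors: int = Field(10, ge=1)
    top_variable: Optional[int] = Field(None, ge=1)


class AffinitySettings(BaseModel):
    K: Optional[int] = Field(None, ge=1)
    mu: float = Field(0.5, gt=0.0)


class FusionSettings(BaseModel):
    method: Literal["hopes", "snf"] = "hopes"
    alpha: float = Field(1.0, ge=0.0)
    beta: float = Field(1.0, ge=0.0)
    ridge: float = Field(1e-8, ge=0.0)
    rho: float = Field(1.0, gt=0.0)
    tol: float = Field(1e-6, gt=0.0)
    max_iter: int = Field(500, ge=1)
    snf_iterations: int = Field(20, ge=1)


class ClusteringSettings(BaseModel):
    k: int = Field(..., ge=2)
    consensus: bool = False
    reps: int = Field(100, ge=2)
    subsample_fraction: float = Field(0.8, gt=0.0, le=1.0)


class FeatureSelectionSettings(BaseModel):
    enabled: bool = True
    n_top: int = Field(15, ge=1)


class PipelineConfig(BaseModel):
    """Validated end-to-end run configuration (YAML-serialisable)."""

    layers: list[str]
    truth: Optional[str] = None
    survival: Optional[str] = None
    categories: Optional[str] = None
    intersect: bool = False
    preprocess: PreprocessConfig = PreprocessConfig()
    affinity: AffinitySettings = AffinitySettings()
    fusion: FusionSettings = FusionSettings()
    clustering: ClusteringSettings
    feature_selection: FeatureSelectionSettings = FeatureSelectionSettings()
    seed: int = 0
    out_dir: str = "hopes_run"

    @field_validator("layers")
    @classmethod
    def _at_least_one(cls, v):
        if not v:
            raise ValueError("at least one layer path is required")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)


def _config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns the output-file manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for p in cfg.layers + [cfg.truth, cfg.survival, cfg.categories]:
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")

    logger.info("reading %d layers", len(cfg.layers))
    raw_layers = [io.read_layer_tsv(p) for p in cfg.layers]
    dataset = align_layers(raw_layers, intersect=cfg.intersect)

    pp = cfg.preprocess
    processed = []
    for layer in dataset:
        layer = filter_missing(layer, pp.max_missing_rate)
        layer = knn_impute(layer, pp.impute_neighbors)
        layer = zscore_normalize(layer)
        if pp.top_variable is not None:
            layer = top_variable_features(layer, pp.top_variable)
        processed.append(layer)
        logger.info("layer %s: %d features after preprocessing", layer.name, layer.n_features)

    if cfg.fusion.method == "hopes":
        model = HOPES(
            processed,
            K=cfg.affinity.K,
            mu=cfg.affinity.mu,
            alpha=cfg.fusion.alpha,
            beta=cfg.fusion.beta,
            ridge=cfg.fusion.ridge,
            rho=cfg.fusion.rho,
            tol=cfg.fusion.tol,
            max_iter=cfg.fusion.max_iter,
            seed=cfg.seed,
        )
    else:
        if len(processed) < 2:
            raise ValueError("SNF fusion needs at least two layers")
        model = SNF(
            processed, K=cfg.affinity.K, mu=cfg.affinity.mu,
            iterations=cfg.fusion.snf_iterations,
        )
    results = model.fit()
    logger.info("fusion done (converged=%s)", results.converged)

    cl = cfg.clustering
    assignment = results.cluster(
        cl.k,
        seed=cfg.seed,
        consensus=cl.consensus,
        reps=cl.reps,
        subsample_fraction=cl.subsample_fraction,
    )

    metrics: dict = {"k": cl.k, "converged": results.converged}
    if cfg.truth:
        truth = io.read_labels_tsv(cfg.truth)
        metrics["nmi"] = nmi(assignment, truth)
        metrics["matched_accuracy"] = matched_accuracy(assignment, truth)
    if cfg.survival:
        surv = io.read_survival_tsv(cfg.survival)
        lr = logrank_test(assignment, surv)
        metrics["logrank_statistic"] = lr.statistic
        metrics["logrank_p_value"] = lr.p_value
    if cfg.categories:
        cats = io.read_categories_tsv(cfg.categories)
        aligned = cats.reindex(assignment.sample_ids)
        if aligned.isna().any():
            raise ValueError("categories file is missing some clustered samples")
        chi = chi_square_association(assignment.labels, aligned.to_numpy())
        metrics["chi2_statistic"] = chi.statistic
        metrics["chi2_p_value"] = chi.p_value

    manifest: dict = {
        "config": cfg.model_dump(),
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "seed": cfg.seed,
        "outputs": {},
    }

    w_path = out / "fused_similarity.tsv"
    io.write_similarity_tsv(results.similarity, results.sample_ids, w_path)
    manifest["outputs"]["similarity"] = str(w_path)

    labels_path = out / "labels.tsv"
    io.write_labels_tsv(assignment, labels_path)
    manifest["outputs"]["labels"] = str(labels_path)

    metrics_path = out / "metrics.json"
    io.write_json(metrics, metrics_path)
    manifest["outputs"]["metrics"] = str(metrics_path)

    if cfg.feature_selection.enabled:
        for layer in processed:
            ranking = results.select_features(
                layer.name, k_clusters=cl.k, n_top=cfg.feature_selection.n_top
            )
            top = select_top_features(ranking, cfg.feature_selection.n_top)
            fpath = out / f"features_{layer.name}.tsv"
            import pandas as pd

            pd.DataFrame(
                {
                    "feature_id": ranking.feature_ids,
                    "score": ranking.scores,
                    "selected": [f in set(top) for f in ranking.feature_ids],
                }
            ).to_csv(fpath, sep="\t", index=False)
            manifest["outputs"][f"features_{layer.name}"] = str(fpath)

    manifest_path = out / "manifest.json"
    io.write_json(manifest, manifest_path)
    return manifest
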