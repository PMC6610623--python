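"""End-to-end pipeline runner with a config file and a reproducibility manifest.

Stage order mirrors the optimised filtering chain: QC metrics → self-label →
train/classify → doublet filter → high-mito filter → (optional) signature
scoring and filter → (optional) embedding/clustering/silhouette.  Every stage
writes its table or report into the run directory and the manifest records
versions, parameters, the seed, per-stage droplet counts and output
checksums, which together suffice to re-execute the identical run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .types import CountMatrix, GeneSet
from .io import read_dense_dge, read_mtx, load_gene_set, write_qc_table
from .qc import compute_qc_table
from .thresholds import apply_standard_filter, flag_doublets, flag_high_mito
from .classify import (
    LabelRule, DEFAULT_FEATURES, assign_training_labels, split_train_test,
    train_classifier, rank_features, classify_droplets,
)
from .clustering import normalize_and_embed, cluster_cells, average_silhouette
from .signature import score_signature, filter_high_signature
from .simulate import SimulationConfig, simulate

__all__ = ["PipelineConfig", "run_pipeline"]

_KNOWN_KEYS = {
    "input", "output_dir", "seed", "n_sshegs", "features", "n_trees",
    "label_max_ngene", "label_mad_k", "label_scale", "label_center_scope",
    "split_ratio", "mito_set", "ribo_set", "hk_set",
    "stages", "standard_filter_only", "doublet_log10", "mito_log10",
    "signature_set", "signature_mad_k",
    "cluster_k", "n_top_genes", "n_components",
}


@dataclass
class PipelineConfig:
    """Pipeline parameters; every field except input/output has a default."""

    input: dict                     # {"kind": "dense"|"mtx"|"simulate", ...}
    output_dir: str
    seed: int = 0
    n_sshegs: int | str = 64
    features: tuple[str, ...] = DEFAULT_FEATURES
    n_trees: int = 500
    label_max_ngene: int = 100
    label_mad_k: float = 2.5
    label_scale: str = "linear"
    label_center_scope: str = "above_cutoff"
    split_ratio: float = 0.75
    mito_set: str | None = None     # gene-set file paths (None -> prefix defaults)
    ribo_set: str | None = None
    hk_set: str | None = None
    stages: tuple[str, ...] = ("classifier", "doublets", "mito")
    standard_filter_only: bool = False
    doublet_log10: bool = False
    mito_log10: bool = False
    signature_set: str | None = None
    signature_mad_k: float = 2.5
    cluster_k: int = 8
    n_top_genes: int = 1000
    n_components: int = 10

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "input" not in d or "output_dir" not in d:
            raise ValueError("config requires 'input' and 'output_dir'")
        return PipelineConfig(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_input(cfg: PipelineConfig) -> tuple[CountMatrix, GeneSet | None]:
    spec = dict(cfg.input)
    kind = spec.pop("kind")
    if kind == "dense":
        return read_dense_dge(spec["path"]), None
    if kind == "mtx":
        return read_mtx(spec["path"]), None
    if kind == "simulate":
        spec.setdefault("seed", cfg.seed)
        dataset = simulate(SimulationConfig.from_dict(spec))
        return dataset.matrix, dataset.planted_sets["housekeeping"]
    raise ValueError(f"unknown input kind {kind!r}")


def run_pipeline(config: PipelineConfig | dict) -> Path:
    """Execute the configured stage chain; returns the run directory."""
    cfg = PipelineConfig.from_dict(config) if isinstance(config, dict) else config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "dropqc_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, n_droplets: int, t0: float, **extra) -> None:
        manifest["stages"].append(
            {"stage": stage, "n_droplets": int(n_droplets),
             "seconds": round(time.time() - t0, 3), **extra}
        )

    t0 = time.time()
    matrix, sim_hk = _load_input(cfg)
    record("load", matrix.n_droplets, t0, n_genes=matrix.n_genes)

    t0 = time.time()
    hk = load_gene_set(cfg.hk_set) if cfg.hk_set else sim_hk
    mito = load_gene_set(cfg.mito_set) if cfg.mito_set else None
    ribo = load_gene_set(cfg.ribo_set) if cfg.ribo_set else None
    table = compute_qc_table(matrix, n_sshegs=cfg.n_sshegs, mito=mito, ribo=ribo, hk=hk)
    write_qc_table(table, out / "qc_table.tsv")
    record("qc_metrics", len(table), t0)

    if cfg.standard_filter_only:
        t0 = time.time()
        report = apply_standard_filter(table)
        report.to_json(out / "standard_filter.json")
        retained = table[table["barcode"].isin(report.retained_barcodes)]
        write_qc_table(retained, out / "retained.tsv")
        record("standard_filter", report.n_retained, t0, n_removed=report.n_removed)
        _finish(manifest, out)
        return out

    retained = table
    if "classifier" in cfg.stages:
        t0 = time.time()
        rule = LabelRule(cfg.label_max_ngene, cfg.label_mad_k, cfg.label_scale,
                         cfg.label_center_scope)
        labeled = assign_training_labels(table, rule)
        train, test = split_train_test(labeled, ratio=cfg.split_ratio, seed=cfg.seed)
        model = train_classifier(train, test, features=tuple(cfg.features),
                                 n_trees=cfg.n_trees, seed=cfg.seed)
        rank_features(model).to_csv(out / "feature_importance.tsv", sep="\t", index=False)
        model.save(out / "classifier.pkl")
        predicted = classify_droplets(model, labeled)
        write_qc_table(predicted, out / "classified.tsv")
        retained = predicted[predicted["predicted_class"] == "cell"]
        record("classifier", len(retained), t0,
               test_sensitivity=model.test_sensitivity,
               test_specificity=model.test_specificity,
               n_removed=int(len(predicted) - len(retained)))

    if "doublets" in cfg.stages:
        t0 = time.time()
        report = flag_doublets(retained, log10_scale=cfg.doublet_log10)
        report.to_json(out / "doublet_filter.json")
        retained = retained[retained["barcode"].isin(report.retained_barcodes)]
        record("doublets", len(retained), t0, n_removed=report.n_removed,
               **report.threshold_values)

    if "mito" in cfg.stages:
        t0 = time.time()
        report = flag_high_mito(retained, log10_scale=cfg.mito_log10)
        report.to_json(out / "mito_filter.json")
        retained = retained[retained["barcode"].isin(report.retained_barcodes)]
        record("mito", len(retained), t0, n_removed=report.n_removed,
               **report.threshold_values)

    if "signature" in cfg.stages and cfg.signature_set:
        t0 = time.time()
        sig = load_gene_set(cfg.signature_set, "signature")
        sub = matrix.subset_droplets(list(retained["barcode"]))
        scores = score_signature(sub, sig)
        scores.to_csv(out / "signature_scores.tsv", sep="\t", index=False)
        report = filter_high_signature(scores, k=cfg.signature_mad_k)
        report.to_json(out / "signature_filter.json")
        retained = retained[retained["barcode"].isin(report.retained_barcodes)]
        record("signature", len(retained), t0, n_removed=report.n_removed)

    write_qc_table(retained, out / "retained.tsv")

    if "cluster" in cfg.stages:
        t0 = time.time()
        sub = matrix.subset_droplets(list(retained["barcode"]))
        embedding = normalize_and_embed(sub, n_top_genes=cfg.n_top_genes,
                                        n_components=cfg.n_components)
        clusters = cluster_cells(embedding, k=cfg.cluster_k, seed=cfg.seed)
        sil = average_silhouette(embedding, clusters)
        pd.DataFrame({
            "barcode": embedding.barcodes, "cluster": clusters.cluster_id,
        }).to_csv(out / "clusters.tsv", sep="\t", index=False)
        record("cluster", len(retained), t0, k=clusters.k, average_silhouette=sil)

    _finish(manifest, out)
    return out


def _finish(manifest: dict, out: Path) -> None:
    for path in sorted(out.glob("*")):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
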