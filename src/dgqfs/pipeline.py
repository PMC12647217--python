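"""End-to-end orchestration: config parsing, staged runs, comparison tables.

A run loads (or synthesizes) a labeled feature matrix, splits it stratified
75/25, builds the correlation graph on the training partition, refines it
with entanglement-weighted centrality selection, trains the MLP on the
selected columns, and writes metrics, diagnostics, the selection trace, the
model archive, per-stage timings and a resolved config snapshot into a fresh
run directory.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import subprocess
import time
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import classifier, evaluation, preprocess, selection, synthetic_data
from .feature_graph import (
    FeatureMatrix,
    build_adjacency,
    export_edge_list,
    load_feature_matrix,
    pearson_correlation,
)
from .quantum_sim import CircuitSpec

__all__ = ["PipelineConfig", "run", "compare", "METHODS"]

METHODS = ("dgqfs", "graph_only", "quantum_only", "random", "pca", "mi", "none")


def _strict(cls, block: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in config block '{name}'")
    return cls(**block)


@dataclass
class PreprocessBlock:
    blur_threshold: float = 100.0
    train_frac: float = 0.75


@dataclass
class GraphBlock:
    tau: float = 0.5


@dataclass
class CircuitBlock:
    n_qubits: int = 2
    n_layers: int = 3
    entangler: str = "CNOT"
    param_seed: int = 7
    batch: int = 64
    measure: str = "entropy"


@dataclass
class RefinementBlock:
    k: int = 64
    beta: float = 0.8
    tau_prune: Optional[float] = None
    max_cycles: int = 5
    literal_update: bool = False


@dataclass
class ClassifierBlock:
    hidden_sizes: tuple[int, int, int] = (256, 128, 64)
    lr_init: float = 0.01
    l2_alpha: float = 0.0005
    batch_size: int = 64
    max_iter: int = 500
    early_stop: bool = True
    val_frac: float = 0.10
    patience: int = 10
    class_weighting: bool = False


@dataclass
class EvaluationBlock:
    bins: int = 16
    average: str = "weighted"


@dataclass
class IOBlock:
    features: Optional[str] = None
    images: Optional[str] = None
    feature_hook: Optional[str] = None
    synthetic: bool = False
    out_dir: str = "runs"


@dataclass
class PipelineConfig:
    seed: int = 0
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    graph: GraphBlock = field(default_factory=GraphBlock)
    circuit: CircuitBlock = field(default_factory=CircuitBlock)
    refinement: RefinementBlock = field(default_factory=RefinementBlock)
    classifier: ClassifierBlock = field(default_factory=ClassifierBlock)
    evaluation: EvaluationBlock = field(default_factory=EvaluationBlock)
    io: IOBlock = field(default_factory=IOBlock)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        blocks = {
            "preprocess": PreprocessBlock,
            "graph": GraphBlock,
            "circuit": CircuitBlock,
            "refinement": RefinementBlock,
            "classifier": ClassifierBlock,
            "evaluation": EvaluationBlock,
            "io": IOBlock,
        }
        kwargs = {}
        for key, block_cls in blocks.items():
            if key in raw:
                kwargs[key] = _strict(block_cls, raw.pop(key) or {}, key)
        if "seed" in raw:
            kwargs["seed"] = int(raw.pop("seed"))
        if raw:
            raise ValueError(f"unknown top-level config keys {sorted(raw)}")
        cfg = cls(**kwargs)
        if isinstance(cfg.classifier.hidden_sizes, list):
            cfg.classifier.hidden_sizes = tuple(cfg.classifier.hidden_sizes)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ValueError(f"malformed config {path}: {exc}") from exc
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def _load_features(config: PipelineConfig) -> FeatureMatrix:
    io = config.io
    if io.features:
        return load_feature_matrix(io.features)
    if io.images:
        return _features_from_images(config)
    if io.synthetic:
        spec = synthetic_data.SyntheticSpec(seed=config.seed)
        return synthetic_data.generate(spec)[0]
    # default: the canonical benchmark
    return synthetic_data.benchmark_default()[0]


def _features_from_images(config: PipelineConfig) -> FeatureMatrix:
    """Image input path: blur-screen + split, then delegate feature extraction.

    Deep feature extraction needs pretrained weights the core deliberately
    does not ship; ``io.feature_hook`` is an external command invoked as
    ``<hook> <manifest_csv> <out_csv>`` that must produce a FeatureMatrix CSV.
    """
    io = config.io
    if not io.feature_hook:
        raise ValueError("image input requires io.feature_hook to produce features")
    path = Path(io.images)
    records = (
        preprocess.read_image_manifest(path)
        if path.is_file()
        else preprocess.read_image_directory(path)
    )
    manifest = preprocess.filter_and_split(
        records, config.preprocess.blur_threshold, config.preprocess.train_frac, config.seed
    )
    out_dir = Path(io.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_csv = out_dir / "split_manifest.csv"
    preprocess.write_manifest_csv(manifest, manifest_csv)
    features_csv = out_dir / "extracted_features.csv"
    subprocess.run(
        [*io.feature_hook.split(), str(manifest_csv), str(features_csv)], check=True
    )
    return load_feature_matrix(features_csv)


def _split(features: FeatureMatrix, train_frac: float, seed: int):
    idx = np.arange(features.n_samples)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, random_state=seed, stratify=features.labels
    )
    return features.subset_rows(np.sort(train_idx)), features.subset_rows(np.sort(test_idx))


def _select_features(
    features: FeatureMatrix, config: PipelineConfig, method: str = "dgqfs"
):
    """Return (selected column indices, SelectionResult-or-None) for a method."""
    k = config.refinement.k
    spec = CircuitSpec(
        n_qubits=config.circuit.n_qubits,
        n_layers=config.circuit.n_layers,
        entangler=config.circuit.entangler,
        param_seed=config.circuit.param_seed,
    )
    if method == "dgqfs":
        graph = build_adjacency(pearson_correlation(features), config.graph.tau)
        cfg = selection.RefinementConfig(
            k=k,
            beta=config.refinement.beta,
            tau_prune=config.refinement.tau_prune,
            max_cycles=config.refinement.max_cycles,
            literal_update=config.refinement.literal_update,
            batch=config.circuit.batch,
            sample_seed=config.seed,
            measure=config.circuit.measure,
        )
        result = selection.refine(features, graph, spec, cfg)
        return result.selected, result
    if method == "none":
        return list(range(features.n_features)), None
    selected = evaluation.baseline_select(
        features,
        method,
        k,
        seed=config.seed,
        tau=config.graph.tau,
        spec=spec,
        batch=config.circuit.batch,
        bins=config.evaluation.bins,
    )
    if method == "pca":
        raise ValueError("pca returns a projection; use compare() which handles it")
    return selected, None


def _fit_eval(train: FeatureMatrix, test: FeatureMatrix, selected, config: PipelineConfig):
    cfg = classifier.MLPConfig(
        hidden_sizes=tuple(config.classifier.hidden_sizes),
        lr_init=config.classifier.lr_init,
        l2_alpha=config.classifier.l2_alpha,
        batch_size=config.classifier.batch_size,
        max_iter=config.classifier.max_iter,
        early_stop=config.classifier.early_stop,
        val_frac=config.classifier.val_frac,
        patience=config.classifier.patience,
        seed=config.seed,
        class_weighting=config.classifier.class_weighting,
    )
    model = classifier.fit(train.subset_columns(selected), cfg)
    pred, _ = classifier.predict(model, test.subset_columns(selected))
    report = evaluation.classification_metrics(
        test.labels, pred, n_classes=max(train.n_classes, test.n_classes)
    )
    return model, report


def _run_dir(base: str | Path, config: PipelineConfig) -> Path:
    digest = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:10]
    path = Path(base) / f"run_{digest}"
    if path.exists():
        shutil.rmtree(path)
    path.mkdir(parents=True)
    return path


def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory with all artifacts."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    features = _load_features(config)
    timings["load"] = time.perf_counter() - t0

    out = _run_dir(config.io.out_dir, config)
    with open(out / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    t0 = time.perf_counter()
    train, test = _split(features, config.preprocess.train_frac, config.seed)
    timings["split"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    graph = build_adjacency(pearson_correlation(train), config.graph.tau)
    export_edge_list(graph, out / "initial_graph_edges.csv")
    timings["graph"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    selected, result = _select_features(train, config, "dgqfs")
    selection.save_selection_result(result, out / "selection.json", train.feature_names)
    sub = train.subset_columns(selected)
    pd.DataFrame(sub.values, columns=sub.feature_names).assign(label=sub.labels).to_csv(
        out / "selected_train_matrix.csv", index=False
    )
    timings["select"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    model, report = _fit_eval(train, test, selected, config)
    classifier.save_model(model, out / "model.joblib")
    pd.DataFrame({"loss": model.history}).to_csv(out / "loss_history.csv", index_label="iter")
    timings["train_eval"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    diag = evaluation.feature_set_diagnostics(train, selected, config.evaluation.bins)
    timings["diagnostics"] = time.perf_counter() - t0

    with open(out / "metrics.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    pd.DataFrame(report.confusion).to_csv(out / "confusion.csv", index=False)
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diag.to_dict(), fh, indent=2)
    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=2)
    return out


def compare(config: PipelineConfig, methods: list[str]) -> pd.DataFrame:
    """Train/evaluate each selection method at equal k on identical splits/seeds.

    Emits one row per method with accuracy/precision/recall/F1 (the
    configured averaging) on the shared test partition.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    features = _load_features(config)
    train, test = _split(features, config.preprocess.train_frac, config.seed)
    avg = config.evaluation.average
    rows = []
    for method in methods:
        if method == "pca":
            from sklearn.decomposition import PCA

            pca = PCA(n_components=config.refinement.k, random_state=config.seed).fit(
                train.values
            )
            names = [f"pc{i}" for i in range(config.refinement.k)]
            tr = FeatureMatrix(pca.transform(train.values), train.labels, names)
            te = FeatureMatrix(pca.transform(test.values), test.labels, names)
            _, report = _fit_eval_direct(tr, te, config)
        else:
            selected, _ = _select_features(train, config, method)
            _, report = _fit_eval(train, test, selected, config)
        rows.append(
            {
                "method": method,
                "accuracy": report.accuracy,
                "precision": getattr(report, f"{avg}_precision"),
                "recall": getattr(report, f"{avg}_recall"),
                "f1": getattr(report, f"{avg}_f1"),
            }
        )
    return pd.DataFrame(rows)


def _fit_eval_direct(train: FeatureMatrix, test: FeatureMatrix, config: PipelineConfig):
    return _fit_eval(train, test, list(range(train.n_features)), config)
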