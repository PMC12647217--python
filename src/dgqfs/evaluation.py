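"""Classification metrics, feature-set diagnostics, and ablation baselines.

Headline precision/recall/F1 are reported both macro-averaged (unweighted
class mean) and support-weighted; per-class values come from one-vs-rest
TP/FP/FN/TN counts of the confusion matrix.  Feature-set diagnostics are the
histogram plug-in mutual information and Shannon entropy (base 2) and the
redundancy index (mean absolute off-diagonal pairwise correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .feature_graph import FeatureMatrix, build_adjacency, pearson_correlation
from .quantum_sim import CircuitSpec, score_all_edges
from .selection import eigenvector_centrality, select_top_k

__all__ = [
    "MetricsReport",
    "FeatureSetDiagnostics",
    "classification_metrics",
    "mutual_information",
    "mutual_information_from_joint",
    "shannon_entropy",
    "redundancy_index",
    "feature_set_diagnostics",
    "baseline_select",
]


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    per_class: pd.DataFrame
    confusion: np.ndarray

    @classmethod
    def from_confusion(cls, confusion: np.ndarray) -> "MetricsReport":
        """Build every metric from the confusion matrix alone.

        Rows are true classes, columns predicted.  A class never predicted
        has an undefined precision; it is reported as 0 with a warning and
        counted in the macro mean.
        """
        conf = np.asarray(confusion, dtype=int)
        if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
            raise ValueError("confusion matrix must be square")
        total = conf.sum()
        if total == 0:
            raise ValueError("empty confusion matrix")
        tp = np.diag(conf).astype(float)
        fp = conf.sum(axis=0) - tp
        fn = conf.sum(axis=1) - tp
        support = conf.sum(axis=1)

        undefined = (tp + fp) == 0
        if np.any(undefined & (support > 0)):
            warnings.warn(
                f"classes {np.flatnonzero(undefined).tolist()} never predicted; "
                "precision reported as 0",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), 0.0)
            recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1e-300), 0.0)
            denom = precision + recall
            f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)

        weights = support / total
        per_class = pd.DataFrame(
            {
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "support": support,
            }
        )
        return cls(
            accuracy=float(tp.sum() / total),
            macro_precision=float(precision.mean()),
            macro_recall=float(recall.mean()),
            macro_f1=float(f1.mean()),
            weighted_precision=float(precision @ weights),
            weighted_recall=float(recall @ weights),
            weighted_f1=float(f1 @ weights),
            per_class=per_class,
            confusion=conf,
        )

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "per_class": self.per_class.to_dict(orient="list"),
            "confusion": self.confusion.tolist(),
        }


@dataclass
class FeatureSetDiagnostics:
    mutual_information: float
    shannon_entropy: float
    redundancy_index: float

    def to_dict(self) -> dict:
        return {
            "mutual_information_bits": self.mutual_information,
            "shannon_entropy_bits": self.shannon_entropy,
            "redundancy_index": self.redundancy_index,
        }


def classification_metrics(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    n_classes: int | None = None,
) -> MetricsReport:
    """Confusion matrix plus the standard per-class and averaged metrics."""
    y_true = np.asarray(true_labels, dtype=int)
    y_pred = np.asarray(predicted_labels, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    return MetricsReport.from_confusion(conf)


def mutual_information_from_joint(joint: np.ndarray) -> float:
    """MI in bits of a joint probability table: sum p log2 p/(px*py)."""
    p = np.asarray(joint, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("joint table must be a probability distribution")
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))


def _bin_indices(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0:
        return np.zeros(x.size, dtype=int)
    idx = np.floor((x - lo) / (hi - lo) * bins).astype(int)
    return np.clip(idx, 0, bins - 1)


def mutual_information(x: Sequence[float], y: Sequence[int], bins: int = 16) -> float:
    """Plug-in MI (bits) between a continuous vector (equal-width binned) and labels."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    xi = _bin_indices(x, bins)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((bins, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    return mutual_information_from_joint(joint / x.size)


def shannon_entropy(x: Sequence[float], bins: int = 16) -> float:
    """Plug-in entropy (bits) of the equal-width binned distribution of x."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty input")
    counts = np.bincount(_bin_indices(x, bins), minlength=bins)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def redundancy_index(selected_values: np.ndarray) -> float:
    """Mean absolute off-diagonal pairwise Pearson correlation of selected features."""
    values = (
        selected_values.values
        if isinstance(selected_values, FeatureMatrix)
        else np.asarray(selected_values, dtype=float)
    )
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("redundancy index needs at least 2 selected features")
    corr = pearson_correlation(values).values
    d = corr.shape[0]
    off = np.abs(corr[np.triu_indices(d, k=1)])
    return float(off.mean())


def feature_set_diagnostics(
    features: FeatureMatrix, selected: Sequence[int], bins: int = 16
) -> FeatureSetDiagnostics:
    """MI / entropy / redundancy of a selected subset.

    MI is reported as the mean over selected features of MI(feature, label);
    entropy as the mean per-feature binned entropy.
    """
    selected = list(selected)
    mi = float(
        np.mean([mutual_information(features.values[:, i], features.labels, bins) for i in selected])
    )
    ent = float(np.mean([shannon_entropy(features.values[:, i], bins) for i in selected]))
    ri = redundancy_index(features.values[:, selected])
    return FeatureSetDiagnostics(mi, ent, ri)


def baseline_select(
    features: FeatureMatrix,
    method: str,
    k: int,
    seed: int = 0,
    tau: float = 0.5,
    spec: CircuitSpec | None = None,
    batch: int = 64,
    bins: int = 16,
):
    """Reference selection strategies for ablation comparisons.

    ``pca`` returns the top-k principal-component projection (a transformed
    matrix); every other method returns a list of k column indices.
    """
    d = features.n_features
    if k > d:
        raise ValueError(f"k={k} exceeds d={d}")
    if method == "pca":
        return PCA(n_components=k, random_state=seed).fit_transform(features.values)
    if method == "mi":
        scores = np.array(
            [mutual_information(features.values[:, i], features.labels, bins) for i in range(d)]
        )
        return [int(i) for i in np.argsort(-scores, kind="stable")[:k]]
    if method == "random":
        rng = np.random.default_rng(seed)
        return [int(i) for i in rng.choice(d, size=k, replace=False)]
    if method == "graph_only":
        graph = build_adjacency(pearson_correlation(features), tau)
        return select_top_k(eigenvector_centrality(graph), k)
    if method == "quantum_only":
        graph = build_adjacency(pearson_correlation(features), tau)
        scores = score_all_edges(
            features, graph, spec or CircuitSpec(param_seed=seed), batch=batch, sample_seed=seed
        )
        node_scores = np.zeros(d)
        for (i, j), e in scores.items():
            node_scores[i] += e
            node_scores[j] += e
        return [int(i) for i in np.argsort(-node_scores, kind="stable")[:k]]
    raise ValueError(f"unknown selection method {method!r}")
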