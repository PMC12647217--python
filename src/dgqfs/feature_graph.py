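"""Correlation feature graph: Pearson correlations and thresholded adjacency.

Features become graph nodes; an undirected edge (i, j) carries weight
|corr(x_i, x_j)| whenever that magnitude strictly exceeds the threshold tau.
The graph is the substrate that the quantum edge re-weighting and centrality
ranking later refine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "CorrelationMatrix",
    "FeatureGraph",
    "pearson_correlation",
    "build_adjacency",
    "graph_stats",
    "load_feature_matrix",
    "save_feature_matrix",
    "export_edge_list",
]


@dataclass
class FeatureMatrix:
    """n x d feature activations with integer class labels.

    ``values`` is unit-free (deep-feature activations or synthetic draws),
    ``labels`` holds classes in [0, C), and ``feature_names`` names columns.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if d < 2:
            raise ValueError("need at least 2 features")
        if n < 3:
            raise ValueError("need at least 3 samples")
        if self.labels.shape != (n,):
            raise ValueError(f"labels shape {self.labels.shape} != ({n},)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN/inf")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def subset_columns(self, columns) -> "FeatureMatrix":
        cols = list(columns)
        return FeatureMatrix(
            self.values[:, cols], self.labels, [self.feature_names[c] for c in cols]
        )

    def subset_rows(self, rows) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(self.values[rows], self.labels[rows], list(self.feature_names))


@dataclass
class CorrelationMatrix:
    """Symmetric d x d Pearson coefficient matrix with unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if np.max(np.abs(v - v.T)) > 1e-10:
            raise ValueError("correlation matrix must be symmetric")
        if np.max(np.abs(np.diag(v) - 1.0)) > 1e-10:
            raise ValueError("correlation matrix diagonal must be 1")
        if np.min(v) < -1.0 - 1e-10 or np.max(v) > 1.0 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)


@dataclass
class FeatureGraph:
    """Weighted undirected feature graph as a dense symmetric adjacency."""

    adjacency: np.ndarray
    tau: float
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.max(np.abs(a - a.T)) > 1e-10:
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.min(a) < 0:
            raise ValueError("adjacency weights must be nonnegative")
        self.adjacency = a
        if self.node_ids is None:
            self.node_ids = np.arange(a.shape[0])
        else:
            self.node_ids = np.asarray(self.node_ids, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> list[tuple[int, int, float]]:
        """Nonzero unordered pairs in ascending (i, j) order."""
        d = self.n_nodes
        return [
            (i, j, float(self.adjacency[i, j]))
            for i in range(d)
            for j in range(i + 1, d)
            if self.adjacency[i, j] > 0
        ]


def pearson_correlation(features: FeatureMatrix | np.ndarray) -> CorrelationMatrix:
    """Column-pairwise Pearson correlation matrix.

    Zero-variance columns cannot carry a correlation; their rows/columns are
    set to 0 (diagonal stays 1) with a warning so downstream graph building
    remains well defined on degenerate inputs.
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    stds = values.std(axis=0)
    degenerate = np.flatnonzero(stds == 0)
    if degenerate.size:
        warnings.warn(
            f"zero-variance columns {degenerate.tolist()} correlate as 0", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(corr)


def build_adjacency(corr: CorrelationMatrix, tau: float = 0.5) -> FeatureGraph:
    """Thresholded adjacency: A_ij = |corr_ij| if strictly > tau and i != j, else 0."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    a = np.abs(corr.values).copy()
    np.fill_diagonal(a, 0.0)
    a[a <= tau] = 0.0
    return FeatureGraph(a, tau=tau)


def graph_stats(graph: FeatureGraph) -> dict:
    """Edge count, density and per-node degree of the graph."""
    a = graph.adjacency
    d = graph.n_nodes
    mask = a > 0
    edge_count = int(mask.sum() // 2)
    possible = d * (d - 1) // 2
    return {
        "edge_count": edge_count,
        "density": edge_count / possible if possible else 0.0,
        "degrees": mask.sum(axis=1).astype(int),
    }


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------


def save_feature_matrix(features: FeatureMatrix, path: str | Path) -> None:
    """Write CSV: one header row of feature names plus a final ``label`` column."""
    df = pd.DataFrame(features.values, columns=features.feature_names)
    df["label"] = features.labels
    df.to_csv(path, index=False)


def load_feature_matrix(
    path: str | Path, labels_path: str | Path | None = None
) -> FeatureMatrix:
    """Read the CSV form; ``labels_path`` supports the two-file variant."""
    df = pd.read_csv(path)
    if labels_path is not None:
        labels = pd.read_csv(labels_path).iloc[:, -1].to_numpy()
        names = list(df.columns)
        values = df.to_numpy(dtype=float)
    else:
        if "label" not in df.columns:
            raise ValueError(f"{path} has no 'label' column and no separate label file given")
        labels = df.pop("label").to_numpy()
        names = list(df.columns)
        values = df.to_numpy(dtype=float)
    return FeatureMatrix(values, labels, names)


def export_edge_list(graph: FeatureGraph, path: str | Path) -> None:
    """Write edges as ``i,j,weight`` text for inspection."""
    with open(path, "w") as fh:
        fh.write("i,j,weight\n")
        for i, j, w in graph.edges():
            fh.write(f"{i},{j},{w:.10g}\n")
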