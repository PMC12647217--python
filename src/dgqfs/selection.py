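"""Dynamic graph refinement and centrality-based feature selection.

One refinement cycle: score the surviving edges with the quantum circuit,
blend those scores into the edge weights (fidelity factor beta), prune weak
edges, recompute eigenvector centrality, and reselect the top-k features.
Cycling stops when the selected set stabilizes or ``max_cycles`` is reached.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .feature_graph import FeatureGraph, FeatureMatrix, graph_stats
from .quantum_sim import CircuitSpec, EntanglementScores, entanglement_score

__all__ = [
    "RefinementConfig",
    "CentralityVector",
    "SelectionResult",
    "PowerIterationError",
    "update_edge_weights",
    "eigenvector_centrality",
    "select_top_k",
    "prune_edges",
    "refine",
    "save_selection_result",
]

_EPS_UNIFORM = 1e-8


@dataclass
class RefinementConfig:
    """Knobs of the refinement loop.

    beta is the fidelity factor in [0, 1]: the updated edge weight is
    beta * w + (1 - beta) * E by default (a convex blend of the classical
    correlation weight w and the entanglement score E), or the literal
    additive form w + (1 - beta) * E when ``literal_update`` is set.
    ``tau_prune`` defaults to the graph's construction threshold.
    """

    k: int
    beta: float = 0.8
    tau_prune: Optional[float] = None
    max_cycles: int = 5
    literal_update: bool = False
    power_tol: float = 1e-9
    power_max_iter: int = 100_000
    batch: int = 64
    sample_seed: int = 0
    measure: str = "entropy"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be positive")
        if self.power_tol <= 0 or self.power_max_iter < 1:
            raise ValueError("power iteration tolerances must be positive")


@dataclass
class CentralityVector:
    """Unit-L2 nonnegative eigenvector-centrality vector with its eigenvalue."""

    values: np.ndarray
    eigenvalue: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.min(v) < -1e-12:
            raise ValueError("centrality entries must be nonnegative")
        norm = np.linalg.norm(v)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("centrality vector must be L2-normalized")
        self.values = np.clip(v, 0.0, None)


@dataclass
class SelectionResult:
    """Outcome of the refinement loop."""

    selected: list[int]
    per_cycle_centrality: list[CentralityVector] = field(default_factory=list)
    per_cycle_graph_stats: list[dict] = field(default_factory=list)
    converged_at: Optional[int] = None
    per_cycle_selected: list[list[int]] = field(default_factory=list)
    hook_results: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")


class PowerIterationError(RuntimeError):
    """Raised when power iteration fails to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray):
        super().__init__(message)
        self.last_iterate = last_iterate


def update_edge_weights(
    graph: FeatureGraph,
    scores: EntanglementScores,
    beta: float,
    literal: bool = False,
) -> FeatureGraph:
    """Blend entanglement scores into the edge weights.

    Default: w <- beta * w + (1 - beta) * E (stays in [0, 1] when both
    inputs do).  Literal mode: w <- w + (1 - beta) * E, the unbounded
    additive form.  Non-edges and unscored edges are untouched.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    a = graph.adjacency.copy()
    for (i, j), e in scores.items():
        if a[i, j] <= 0:
            raise ValueError(f"score given for non-edge ({i}, {j})")
        w = a[i, j]
        new = w + (1.0 - beta) * e if literal else beta * w + (1.0 - beta) * e
        a[i, j] = a[j, i] = new
    return FeatureGraph(a, tau=graph.tau, node_ids=graph.node_ids)


def eigenvector_centrality(
    graph: FeatureGraph, tol: float = 1e-9, max_iter: int = 100_000
) -> CentralityVector:
    """Principal-eigenvector centrality of the weighted adjacency.

    Power iteration runs on A + eps*J + s*I, where eps*J (eps = 1e-8,
    all-ones J) makes the matrix irreducible so the Perron vector is unique
    on disconnected graphs, and the spectral shift s = max row sum keeps the
    dominant eigenvalue strictly largest in magnitude (bipartite graphs have
    a -lambda_max eigenvalue that otherwise makes the iteration oscillate).
    The shift leaves eigenvectors unchanged; the reported eigenvalue is the
    Rayleigh quotient with respect to A + eps*J.
    """
    a = graph.adjacency
    d = a.shape[0]
    eps = _EPS_UNIFORM
    shift = float((a.sum(axis=1) + eps * d).max())
    if shift <= 0:
        shift = 1.0
    x = np.full(d, 1.0 / np.sqrt(d))
    for _ in range(max_iter):
        y = a @ x + eps * x.sum() + shift * x
        y /= np.linalg.norm(y)
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    else:
        raise PowerIterationError(
            f"power iteration did not converge within {max_iter} iterations", x
        )
    eigenvalue = float(x @ (a @ x) + eps * x.sum() ** 2)
    return CentralityVector(values=x, eigenvalue=eigenvalue)


def select_top_k(centrality: CentralityVector, k: int) -> list[int]:
    """Indices of the k largest centralities, descending, ties by ascending index."""
    if k <= 0:
        raise ValueError("k must be positive")
    values = centrality.values
    if k > values.size:
        raise ValueError(f"k={k} exceeds number of features {values.size}")
    order = np.argsort(-values, kind="stable")
    return [int(i) for i in order[:k]]


def prune_edges(graph: FeatureGraph, tau_prune: float) -> FeatureGraph:
    """Zero every weight strictly below tau_prune (weights equal to it survive)."""
    a = graph.adjacency.copy()
    a[a < tau_prune] = 0.0
    np.fill_diagonal(a, 0.0)
    return FeatureGraph(a, tau=graph.tau, node_ids=graph.node_ids)


def refine(
    features: FeatureMatrix,
    graph: FeatureGraph,
    spec: CircuitSpec,
    cfg: RefinementConfig,
    classifier_hook: Optional[Callable[[list[int], int], object]] = None,
) -> SelectionResult:
    """Iterative refinement: score -> update -> prune -> centrality -> top-k.

    The per-pair entanglement score depends only on the data, circuit spec
    and row sample, so scores are memoized across cycles.  Convergence is
    declared when two consecutive cycles select the same feature set.
    ``classifier_hook(selected, cycle)``, if given, is called once per cycle
    (e.g. to retrain a classifier on the current subset); its return values
    are recorded in the result.
    """
    tau_prune = cfg.tau_prune if cfg.tau_prune is not None else graph.tau
    memo: dict[tuple[int, int], float] = {}
    prev_selected: Optional[list[int]] = None
    result = SelectionResult(selected=[])
    warned_empty = False
    for cycle in range(1, cfg.max_cycles + 1):
        edges = [(i, j) for i, j, _ in graph.edges()]
        for pair in edges:
            if pair not in memo:
                memo[pair] = entanglement_score(
                    features, pair, spec, cfg.batch, cfg.sample_seed, cfg.measure
                )
        scores = EntanglementScores({p: memo[p] for p in edges}, measure=cfg.measure)
        graph = update_edge_weights(graph, scores, cfg.beta, cfg.literal_update)
        graph = prune_edges(graph, tau_prune)
        if not graph.edges() and not warned_empty:
            warnings.warn(
                f"graph became empty at cycle {cycle}; centrality falls back to the "
                "uniform eps-coupling and selection is by index order",
                stacklevel=2,
            )
            warned_empty = True
        centrality = eigenvector_centrality(graph, cfg.power_tol, cfg.power_max_iter)
        selected = select_top_k(centrality, cfg.k)
        result.per_cycle_centrality.append(centrality)
        result.per_cycle_graph_stats.append(
            {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in graph_stats(graph).items()}
        )
        result.per_cycle_selected.append(selected)
        if classifier_hook is not None:
            result.hook_results.append(classifier_hook(selected, cycle))
        result.selected = selected
        if prev_selected is not None and selected == prev_selected:
            result.converged_at = cycle
            break
        prev_selected = selected
    return result


def save_selection_result(
    result: SelectionResult, path: str | Path, feature_names: Optional[list[str]] = None
) -> None:
    """Serialize the selection outcome (indices, names, eigenvalue trace) as JSON."""
    payload = {
        "selected": result.selected,
        "selected_names": [feature_names[i] for i in result.selected]
        if feature_names
        else None,
        "converged_at": result.converged_at,
        "per_cycle_eigenvalues": [c.eigenvalue for c in result.per_cycle_centrality],
        "per_cycle_edge_counts": [s["edge_count"] for s in result.per_cycle_graph_stats],
        "per_cycle_selected": result.per_cycle_selected,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
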