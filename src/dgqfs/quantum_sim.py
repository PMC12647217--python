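"""Statevector simulation of data re-uploading circuits and entanglement measures.

Feature values enter the circuit through angle encoding: a min-max scaled
value v in [0, 1] becomes a single-qubit rotation RY(pi*v).  Each layer of the
circuit re-encodes the data, applies a block of seeded trainable RY rotations,
and entangles neighbouring qubits with CNOT or CZ gates along a linear chain.
The entanglement generated between the two feature-carrying qubits is scored
either by the von Neumann entropy of one qubit's reduced density matrix
(normalized to [0, 1] by the 1-bit maximum) or by the Wootters concurrence.

Qubit ordering convention: qubit 0 is the leftmost (most significant) position
in the ket, so ``|10>`` means qubit 0 in state 1 and qubit 1 in state 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

__all__ = [
    "CircuitSpec",
    "QuantumState",
    "EntanglementScores",
    "encode_layer",
    "entangle_layer",
    "reuploading_circuit",
    "density_and_partial_trace",
    "von_neumann_entropy",
    "concurrence",
    "entanglement_score",
    "score_all_edges",
    "block_entanglement_scores",
    "circuit_diagram",
]

_NORM_TOL = 1e-10
_HERM_TOL = 1e-8
MAX_QUBITS = 12

_SY = np.array([[0.0, -1.0j], [1.0j, 0.0]])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CircuitSpec:
    """Configuration of a data re-uploading circuit.

    ``trainable_params`` are per-layer, per-qubit RY angles.  They are seeded
    constants rather than optimized quantities: the selection pipeline defines
    no training loss for the circuit, and a fixed seed keeps every score
    reproducible.  Pass explicit angles to override the seeded draw.
    """

    n_qubits: int = 2
    n_layers: int = 3
    entangler: Literal["CNOT", "CZ"] = "CNOT"
    param_seed: int = 0
    trainable_params: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_qubits < 1:
            raise ValueError("n_qubits must be positive")
        if self.n_qubits > MAX_QUBITS:
            raise ValueError(f"n_qubits={self.n_qubits} exceeds simulator guard {MAX_QUBITS}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be positive")
        if self.entangler not in ("CNOT", "CZ"):
            raise ValueError(f"unknown entangler {self.entangler!r}")
        if self.trainable_params is not None:
            p = np.asarray(self.trainable_params, dtype=float)
            if p.shape != (self.n_layers, self.n_qubits):
                raise ValueError(
                    f"trainable_params shape {p.shape} != ({self.n_layers}, {self.n_qubits})"
                )
            if not np.all(np.isfinite(p)):
                raise ValueError("trainable_params must be finite")
            self.trainable_params = p

    def resolved_params(self) -> np.ndarray:
        """Return the (n_layers, n_qubits) angle array, drawing seeded values if unset."""
        if self.trainable_params is not None:
            return self.trainable_params
        rng = np.random.default_rng(self.param_seed)
        return rng.uniform(0.0, 2.0 * np.pi, size=(self.n_layers, self.n_qubits))


@dataclass
class QuantumState:
    """Pure state of ``n_qubits`` qubits as a normalized complex amplitude vector."""

    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=complex).ravel()
        n = int(np.log2(amp.size))
        if 2**n != amp.size:
            raise ValueError(f"amplitude vector length {amp.size} is not a power of two")
        norm = np.linalg.norm(amp)
        if abs(norm - 1.0) > _NORM_TOL:
            raise ValueError(f"state norm {norm} deviates from 1 beyond {_NORM_TOL}")
        self.amplitudes = amp

    @property
    def n_qubits(self) -> int:
        return int(np.log2(self.amplitudes.size))

    @classmethod
    def zero(cls, n_qubits: int) -> "QuantumState":
        amp = np.zeros(2**n_qubits, dtype=complex)
        amp[0] = 1.0
        return cls(amp)


@dataclass
class EntanglementScores:
    """Sparse symmetric map (i, j) -> score in [0, 1] over graph edges."""

    scores: dict[tuple[int, int], float]
    measure: Literal["entropy", "concurrence"] = "entropy"

    def __post_init__(self) -> None:
        clean: dict[tuple[int, int], float] = {}
        for (i, j), v in self.scores.items():
            if i == j:
                raise ValueError("self-pairs are not scorable")
            key = (min(i, j), max(i, j))
            v = float(v)
            if not (-1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"score {v} for pair {key} outside [0, 1]")
            clean[key] = min(max(v, 0.0), 1.0)
        self.scores = clean

    def get(self, i: int, j: int, default: float | None = None) -> float | None:
        return self.scores.get((min(i, j), max(i, j)), default)

    def items(self):
        return self.scores.items()

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.scores


# ---------------------------------------------------------------------------
# gate primitives
# ---------------------------------------------------------------------------


def _ry(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -s], [s, c]], dtype=complex)


def _apply_single_qubit(amplitudes: np.ndarray, gate: np.ndarray, qubit: int, n: int) -> np.ndarray:
    psi = amplitudes.reshape((2,) * n)
    psi = np.moveaxis(psi, qubit, 0)
    shape = psi.shape
    psi = gate @ psi.reshape(2, -1)
    psi = np.moveaxis(psi.reshape(shape), 0, qubit)
    return psi.reshape(-1)


def _apply_cnot(amplitudes: np.ndarray, control: int, target: int, n: int) -> np.ndarray:
    psi = amplitudes.reshape((2,) * n).copy()
    sel: list[slice | int] = [slice(None)] * n
    sel[control] = 1
    psi[tuple(sel)] = np.flip(psi[tuple(sel)], axis=target if target < control else target - 1)
    return psi.reshape(-1)


def _apply_cz(amplitudes: np.ndarray, control: int, target: int, n: int) -> np.ndarray:
    psi = amplitudes.reshape((2,) * n).copy()
    sel: list[slice | int] = [slice(None)] * n
    sel[control] = 1
    sel[target] = 1
    psi[tuple(sel)] = -psi[tuple(sel)]
    return psi.reshape(-1)


# ---------------------------------------------------------------------------
# circuit operations
# ---------------------------------------------------------------------------


def encode_layer(state: QuantumState, angles: Iterable[float]) -> QuantumState:
    """Apply RY(angle_q) to every qubit q (angle encoding of one value per qubit)."""
    angles = np.asarray(list(angles), dtype=float)
    n = state.n_qubits
    if angles.size != n:
        raise ValueError(f"expected {n} angles, got {angles.size}")
    amp = state.amplitudes
    for q, theta in enumerate(angles):
        amp = _apply_single_qubit(amp, _ry(theta), q, n)
    return QuantumState(amp)


def entangle_layer(state: QuantumState, entangler: str = "CNOT") -> QuantumState:
    """Entangle along the linear chain q0->q1, q1->q2, ... with CNOT or CZ."""
    n = state.n_qubits
    if n < 2:
        raise ValueError("entangling layer requires at least 2 qubits")
    amp = state.amplitudes
    apply = {"CNOT": _apply_cnot, "CZ": _apply_cz}.get(entangler)
    if apply is None:
        raise ValueError(f"unknown entangler {entangler!r}")
    for q in range(n - 1):
        amp = apply(amp, q, q + 1, n)
    return QuantumState(amp)


def reuploading_circuit(spec: CircuitSpec, data_angles: Iterable[float]) -> QuantumState:
    """Run the full L-layer re-uploading circuit from |0...0>.

    Per layer: re-encode the data angles, apply the layer's trainable RY
    block, then the entangling chain.
    """
    data_angles = np.asarray(list(data_angles), dtype=float)
    if data_angles.size != spec.n_qubits:
        raise ValueError(f"expected {spec.n_qubits} data angles, got {data_angles.size}")
    params = spec.resolved_params()
    state = QuantumState.zero(spec.n_qubits)
    for layer in range(spec.n_layers):
        state = encode_layer(state, data_angles)
        state = encode_layer(state, params[layer])
        if spec.n_qubits >= 2:
            state = entangle_layer(state, spec.entangler)
    return state


# ---------------------------------------------------------------------------
# density matrices and entanglement measures
# ---------------------------------------------------------------------------


def density_and_partial_trace(state: QuantumState, keep: Iterable[int]) -> np.ndarray:
    """Reduced density matrix of the ``keep`` qubits (complement traced out).

    Rows/columns are ordered by the sorted kept-qubit indices.
    """
    keep = sorted(set(int(k) for k in keep))
    n = state.n_qubits
    if not keep:
        raise ValueError("keep must be nonempty")
    if keep[0] < 0 or keep[-1] >= n:
        raise ValueError(f"keep indices {keep} out of range for {n} qubits")
    psi = state.amplitudes.reshape((2,) * n)
    bra_axes = [q + n if q in keep else q for q in range(n)]
    out_axes = keep + [q + n for q in keep]
    rho = np.einsum(psi, list(range(n)), psi.conj(), bra_axes, out_axes)
    m = len(keep)
    return rho.reshape(2**m, 2**m)


def _check_density(rho: np.ndarray) -> np.ndarray:
    rho = np.asarray(rho, dtype=complex)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError("density matrix must be square")
    if np.max(np.abs(rho - rho.conj().T)) > _HERM_TOL:
        raise ValueError("density matrix is not Hermitian within tolerance")
    return rho


def von_neumann_entropy(rho: np.ndarray) -> float:
    """Von Neumann entropy -Tr(rho log2 rho) in bits (0 log 0 := 0)."""
    rho = _check_density(rho)
    evals = np.linalg.eigvalsh(rho)
    evals = np.clip(evals.real, 0.0, 1.0)
    nz = evals[evals > 1e-12]
    return float(-np.sum(nz * np.log2(nz)))


def concurrence(rho: np.ndarray) -> float:
    """Wootters concurrence of a two-qubit density matrix.

    C = max(0, l1 - l2 - l3 - l4) where the l's are the square roots of the
    eigenvalues of rho (sY x sY) rho* (sY x sY), in decreasing order.
    Numerically the l's are obtained as the singular values of
    sqrt(rho) (sY x sY) sqrt(rho)*, which has the same spectrum but avoids
    taking square roots of near-zero eigenvalues.
    """
    rho = _check_density(rho)
    if rho.shape != (4, 4):
        raise ValueError(f"concurrence requires a 4x4 two-qubit state, got {rho.shape}")
    evals, vecs = np.linalg.eigh(rho)
    sqrt_rho = (vecs * np.sqrt(np.clip(evals, 0.0, None))) @ vecs.conj().T
    yy = np.kron(_SY, _SY)
    lam = np.linalg.svd(sqrt_rho @ yy @ sqrt_rho.conj(), compute_uv=False)
    c = lam[0] - lam[1] - lam[2] - lam[3]
    return float(min(max(c, 0.0), 1.0))


# ---------------------------------------------------------------------------
# batched two-qubit fast path (used by the per-pair scorer)
# ---------------------------------------------------------------------------


def _batch_ry_mats(thetas: np.ndarray) -> np.ndarray:
    c, s = np.cos(thetas / 2.0), np.sin(thetas / 2.0)
    mats = np.empty(thetas.shape + (2, 2), dtype=complex)
    mats[..., 0, 0] = c
    mats[..., 0, 1] = -s
    mats[..., 1, 0] = s
    mats[..., 1, 1] = c
    return mats


def _pair_states(theta0: np.ndarray, theta1: np.ndarray, spec: CircuitSpec) -> np.ndarray:
    """Vectorized two-qubit re-uploading circuit over a batch of angle pairs.

    Returns the final states as a (batch, 2, 2) amplitude tensor indexed by
    (qubit0, qubit1); matches :func:`reuploading_circuit` row by row.
    """
    if spec.n_qubits != 2:
        raise ValueError("pairwise scoring uses a 2-qubit circuit")
    theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
    theta1 = np.atleast_1d(np.asarray(theta1, dtype=float))
    batch = theta0.size
    params = spec.resolved_params()
    psi = np.zeros((batch, 2, 2), dtype=complex)
    psi[:, 0, 0] = 1.0
    m0 = _batch_ry_mats(theta0)
    m1 = _batch_ry_mats(theta1)
    for layer in range(spec.n_layers):
        psi = np.einsum("bik,bkj->bij", m0, psi)
        psi = np.einsum("bjk,bik->bij", m1, psi)
        p0 = _ry(params[layer, 0])
        p1 = _ry(params[layer, 1])
        psi = np.einsum("ik,bkj->bij", p0, psi)
        psi = np.einsum("jk,bik->bij", p1, psi)
        if spec.entangler == "CNOT":
            psi[:, 1, :] = psi[:, 1, ::-1]
        else:
            psi[:, 1, 1] = -psi[:, 1, 1]
    return psi


def _batch_entropy_qubit0(psi: np.ndarray) -> np.ndarray:
    """Entropy (bits) of qubit 0's reduction, per batched pure 2-qubit state."""
    rho = np.einsum("bij,bkj->bik", psi, psi.conj())
    det = (rho[:, 0, 0] * rho[:, 1, 1] - rho[:, 0, 1] * rho[:, 1, 0]).real
    disc = np.sqrt(np.clip(0.25 - det, 0.0, None))
    lam1 = np.clip(0.5 + disc, 0.0, 1.0)
    lam2 = np.clip(0.5 - disc, 0.0, 1.0)
    out = np.zeros(psi.shape[0])
    for lam in (lam1, lam2):
        mask = lam > 1e-12
        out[mask] -= lam[mask] * np.log2(lam[mask])
    return out


def _batch_concurrence(psi: np.ndarray) -> np.ndarray:
    """Concurrence per batched pure 2-qubit state: C = 2|ad - bc|."""
    a, b, c, d = psi[:, 0, 0], psi[:, 0, 1], psi[:, 1, 0], psi[:, 1, 1]
    return np.clip(2.0 * np.abs(a * d - b * c), 0.0, 1.0)


# ---------------------------------------------------------------------------
# feature-pair scoring
# ---------------------------------------------------------------------------


def _minmax_angles(column: np.ndarray, name: str = "column") -> np.ndarray:
    lo, hi = float(np.min(column)), float(np.max(column))
    if hi - lo <= 0.0:
        warnings.warn(f"constant {name}: encoding angle 0 for all rows", stacklevel=3)
        return np.zeros_like(column, dtype=float)
    return np.pi * (column - lo) / (hi - lo)


def _sample_rows(n: int, batch: int, sample_seed: int) -> np.ndarray:
    take = min(batch, n)
    rng = np.random.default_rng(sample_seed)
    return rng.choice(n, size=take, replace=False)


def entanglement_score(
    features,
    pair: tuple[int, int],
    spec: CircuitSpec | None = None,
    batch: int = 64,
    sample_seed: int = 0,
    measure: str = "entropy",
) -> float:
    """Mean per-row entanglement generated between two feature-carrying qubits.

    Each selected row's two values are min-max scaled (over the full column)
    to [0, 1], encoded as angles pi*v on a 2-qubit re-uploading circuit, and
    the chosen measure of the resulting state is averaged over rows: the von
    Neumann entropy of qubit 0's reduction (normalized by its 1-bit maximum)
    or the concurrence of the pure two-qubit state.
    """
    values = features.values if hasattr(features, "values") else np.asarray(features, float)
    i, j = pair
    if i == j:
        raise ValueError("cannot score a feature against itself")
    # canonical pair order: the lower-index feature always drives qubit 0,
    # making the score symmetric despite the directed CNOT chain
    i, j = (i, j) if i < j else (j, i)
    if spec is None:
        spec = CircuitSpec()
    if measure not in ("entropy", "concurrence"):
        raise ValueError(f"unknown measure {measure!r}")
    if batch < 1:
        raise ValueError("batch must be positive")
    ang_i = _minmax_angles(values[:, i], f"column {i}")
    ang_j = _minmax_angles(values[:, j], f"column {j}")
    rows = _sample_rows(values.shape[0], batch, sample_seed)
    psi = _pair_states(ang_i[rows], ang_j[rows], spec)
    if measure == "entropy":
        per_row = _batch_entropy_qubit0(psi)
    else:
        per_row = _batch_concurrence(psi)
    return float(np.clip(per_row.mean(), 0.0, 1.0))


def score_all_edges(
    features,
    graph,
    spec: CircuitSpec | None = None,
    batch: int = 64,
    sample_seed: int = 0,
    measure: str = "entropy",
    mode: str = "pair",
) -> EntanglementScores:
    """Entanglement scores for every edge of the feature graph.

    Only pairs with nonzero adjacency are scored, keeping cost O(|E| * batch).
    ``mode='block'`` is an experimental alternative that runs one joint
    ``spec.n_qubits``-qubit circuit per group of connected nodes and scores
    each in-block pair by the entropy of its two-qubit reduced state
    (normalized by the 2-bit maximum); cross-block edges fall back to the
    pairwise circuit.
    """
    adjacency = graph.adjacency
    d = adjacency.shape[0]
    edges = [(i, j) for i in range(d) for j in range(i + 1, d) if adjacency[i, j] > 0]
    if spec is None:
        spec = CircuitSpec()
    if mode == "pair":
        scores = {
            (i, j): entanglement_score(features, (i, j), spec, batch, sample_seed, measure)
            for (i, j) in edges
        }
        return EntanglementScores(scores, measure=measure)
    if mode != "block":
        raise ValueError(f"unknown scoring mode {mode!r}")
    return _score_edges_blockwise(features, edges, spec, batch, sample_seed, measure)


def _score_edges_blockwise(features, edges, spec, batch, sample_seed, measure):
    """Joint-circuit scoring: consecutive groups of edge-touching nodes share one circuit."""
    values = features.values if hasattr(features, "values") else np.asarray(features, float)
    nodes = sorted({q for e in edges for q in e})
    q = spec.n_qubits
    blocks = [nodes[s : s + q] for s in range(0, len(nodes), q)]
    node_to_block = {n: b for b, blk in enumerate(blocks) for n in blk}
    rows = _sample_rows(values.shape[0], batch, sample_seed)
    angle_cols = {n: _minmax_angles(values[:, n], f"column {n}")[rows] for n in nodes}
    scores: dict[tuple[int, int], float] = {}
    block_states: dict[int, list[QuantumState]] = {}
    for (i, j) in edges:
        if node_to_block[i] != node_to_block[j]:
            scores[(i, j)] = entanglement_score(
                features, (i, j), CircuitSpec(2, spec.n_layers, spec.entangler, spec.param_seed),
                batch, sample_seed, measure,
            )
            continue
        b = node_to_block[i]
        blk = blocks[b]
        if b not in block_states:
            blk_spec = CircuitSpec(len(blk), spec.n_layers, spec.entangler, spec.param_seed) \
                if len(blk) != q else spec
            data = np.stack([angle_cols[n] for n in blk], axis=1)
            block_states[b] = [reuploading_circuit(blk_spec, row) for row in data] \
                if len(blk) >= 2 else []
        states = block_states[b]
        if not states:
            scores[(i, j)] = 0.0
            continue
        ki, kj = blk.index(i), blk.index(j)
        per_row = [
            von_neumann_entropy(density_and_partial_trace(s, [ki, kj])) / 2.0 for s in states
        ]
        scores[(i, j)] = float(np.clip(np.mean(per_row), 0.0, 1.0))
    return EntanglementScores(scores, measure=measure)


def circuit_diagram(spec: CircuitSpec) -> str:
    """Plain-text sketch of the re-uploading circuit, one line per qubit."""
    lines = []
    ent = "X" if spec.entangler == "CNOT" else "Z"
    for qubit in range(spec.n_qubits):
        cells = []
        for _ in range(spec.n_layers):
            cells.append("RY(x)-RY(p)")
            if spec.n_qubits >= 2:
                if qubit == 0:
                    cells.append("*")
                elif qubit == spec.n_qubits - 1:
                    cells.append(ent)
                else:
                    cells.append(f"{ent}*")
        lines.append(f"q{qubit}: |0> " + "--".join(cells))
    return "\n".join(lines)
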