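"""Statevector circuit core: gates, reductions, entanglement measures, scoring."""

import numpy as np
import pytest

from dgqfs.feature_graph import CorrelationMatrix, build_adjacency
from dgqfs.quantum_sim import (
    CircuitSpec,
    QuantumState,
    concurrence,
    density_and_partial_trace,
    encode_layer,
    entangle_layer,
    entanglement_score,
    reuploading_circuit,
    score_all_edges,
    von_neumann_entropy,
)

from oracles import oracle_circuit

SQ2 = 1.0 / np.sqrt(2.0)


class TestGateLayers:
    def test_zero_angles_identity(self):
        state = encode_layer(QuantumState.zero(3), [0.0, 0.0, 0.0])
        np.testing.assert_allclose(state.amplitudes[0], 1.0)

    def test_ry_pi_flips(self):
        state = encode_layer(QuantumState.zero(1), [np.pi])
        np.testing.assert_allclose(np.abs(state.amplitudes), [0.0, 1.0], atol=1e-12)

    def test_ry_pi_over_3_closed_form(self):
        state = encode_layer(QuantumState.zero(1), [np.pi / 3])
        np.testing.assert_allclose(
            state.amplitudes.real, [np.sqrt(3) / 2, 0.5], atol=1e-12
        )

    def test_cnot_truth_table(self):
        ten = QuantumState(np.array([0, 0, 1, 0], dtype=complex))  # |10>
        out = entangle_layer(ten, "CNOT")
        np.testing.assert_allclose(out.amplitudes, [0, 0, 0, 1], atol=1e-12)  # |11>

    def test_cz_phase_flip(self):
        eleven = QuantumState(np.array([0, 0, 0, 1], dtype=complex))
        out = entangle_layer(eleven, "CZ")
        np.testing.assert_allclose(out.amplitudes, [0, 0, 0, -1], atol=1e-12)

    def test_bell_preparation(self):
        plus = encode_layer(QuantumState.zero(2), [np.pi / 2, 0.0])
        bell = entangle_layer(plus, "CNOT")
        np.testing.assert_allclose(bell.amplitudes, [SQ2, 0, 0, SQ2], atol=1e-12)

    def test_angle_count_mismatch(self):
        with pytest.raises(ValueError):
            encode_layer(QuantumState.zero(2), [0.1])

    def test_single_qubit_entangle_rejected(self):
        with pytest.raises(ValueError):
            entangle_layer(QuantumState.zero(1), "CNOT")

    def test_norm_preserved_on_random_states(self, rng):
        for _ in range(20):
            amp = rng.normal(size=8) + 1j * rng.normal(size=8)
            amp /= np.linalg.norm(amp)
            state = QuantumState(amp)
            out = entangle_layer(
                encode_layer(state, rng.uniform(0, 2 * np.pi, 3)),
                "CNOT" if rng.random() < 0.5 else "CZ",
            )
            assert abs(np.linalg.norm(out.amplitudes) - 1.0) < 1e-10


class TestReuploadingCircuit:
    def test_identity_path(self):
        spec = CircuitSpec(2, 1, "CNOT", trainable_params=np.zeros((1, 2)))
        state = reuploading_circuit(spec, [0.0, 0.0])
        np.testing.assert_allclose(state.amplitudes, [1, 0, 0, 0], atol=1e-12)

    def test_bell_from_data_angles(self):
        spec = CircuitSpec(2, 1, "CNOT", trainable_params=np.zeros((1, 2)))
        state = reuploading_circuit(spec, [np.pi / 2, 0.0])
        np.testing.assert_allclose(state.amplitudes, [SQ2, 0, 0, SQ2], atol=1e-12)

    @pytest.mark.parametrize("n_qubits", [2, 3])
    @pytest.mark.parametrize("entangler", ["CNOT", "CZ"])
    def test_matches_matrix_product_oracle(self, rng, n_qubits, entangler):
        for trial in range(7):
            spec = CircuitSpec(
                n_qubits, int(rng.integers(1, 4)), entangler, param_seed=int(rng.integers(1e6))
            )
            data = rng.uniform(0, np.pi, n_qubits)
            got = reuploading_circuit(spec, data).amplitudes
            np.testing.assert_allclose(got, oracle_circuit(spec, data), atol=1e-12)


class TestPartialTrace:
    def test_product_state_reduction_is_pure(self):
        state = QuantumState(np.array([0, 1, 0, 0], dtype=complex))  # |01>
        rho = density_and_partial_trace(state, [0])
        np.testing.assert_allclose(rho, [[1, 0], [0, 0]], atol=1e-12)

    def test_bell_reduction_maximally_mixed(self):
        bell = QuantumState(np.array([SQ2, 0, 0, SQ2]))
        rho = density_and_partial_trace(bell, [0])
        np.testing.assert_allclose(rho, np.eye(2) / 2, atol=1e-12)

    def test_keep_all_is_projector(self, rng):
        amp = rng.normal(size=4) + 1j * rng.normal(size=4)
        amp /= np.linalg.norm(amp)
        state = QuantumState(amp)
        rho = density_and_partial_trace(state, [0, 1])
        np.testing.assert_allclose(rho, np.outer(amp, amp.conj()), atol=1e-12)
        assert np.linalg.matrix_rank(rho, tol=1e-10) == 1

    def test_invalid_index(self):
        with pytest.raises(ValueError):
            density_and_partial_trace(QuantumState.zero(2), [2])


class TestEntropy:
    def test_pure_state_zero(self):
        assert von_neumann_entropy(np.array([[1, 0], [0, 0]], dtype=complex)) == 0.0

    def test_maximally_mixed_one_bit(self):
        assert von_neumann_entropy(np.eye(2) / 2) == pytest.approx(1.0, abs=1e-12)

    def test_three_quarters_closed_form(self):
        rho = np.diag([0.75, 0.25]).astype(complex)
        expected = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert von_neumann_entropy(rho) == pytest.approx(expected, abs=1e-12)
        assert von_neumann_entropy(rho) == pytest.approx(0.811278, abs=1e-6)

    def test_non_hermitian_rejected(self):
        with pytest.raises(ValueError, match="Hermitian"):
            von_neumann_entropy(np.array([[0.5, 1.0], [0.0, 0.5]]))

    def test_single_qubit_bounds_on_random_reductions(self, rng):
        for _ in range(20):
            amp = rng.normal(size=8) + 1j * rng.normal(size=8)
            amp /= np.linalg.norm(amp)
            s = von_neumann_entropy(density_and_partial_trace(QuantumState(amp), [1]))
            assert -1e-12 <= s <= 1.0 + 1e-12

    def test_product_cut_gives_zero(self):
        # |+>|0> is a product across the cut
        plus0 = encode_layer(QuantumState.zero(2), [np.pi / 2, 0.0])
        s = von_neumann_entropy(density_and_partial_trace(plus0, [0]))
        assert s == pytest.approx(0.0, abs=1e-10)


class TestConcurrence:
    def test_product_state_zero(self):
        rho = density_and_partial_trace(QuantumState.zero(2), [0, 1])
        assert concurrence(rho) == 0.0

    def test_bell_state_one(self):
        bell = QuantumState(np.array([SQ2, 0, 0, SQ2]))
        rho = density_and_partial_trace(bell, [0, 1])
        assert concurrence(rho) == pytest.approx(1.0, abs=1e-9)

    def test_schmidt_diagonal_closed_form(self):
        a, d = np.sqrt(3) / 2, 0.5
        psi = np.array([a, 0, 0, d], dtype=complex)
        rho = np.outer(psi, psi.conj())
        assert concurrence(rho) == pytest.approx(2 * a * d, abs=1e-12)

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ValueError):
            concurrence(np.eye(2) / 2)

    def test_entropy_concurrence_monotone_on_schmidt_sweep(self):
        angles = np.linspace(0.0, np.pi / 2, 25)
        entropies, concurrences = [], []
        for t in angles:
            psi = np.array([np.cos(t / 2), 0, 0, np.sin(t / 2)], dtype=complex)
            state = QuantumState(psi)
            entropies.append(von_neumann_entropy(density_and_partial_trace(state, [0])))
            concurrences.append(concurrence(np.outer(psi, psi.conj())))
        entropies, concurrences = np.array(entropies), np.array(concurrences)
        # zero together at the product end, maximal together at the Bell end
        assert entropies[0] == pytest.approx(0.0, abs=1e-10)
        assert concurrences[0] == pytest.approx(0.0, abs=1e-10)
        assert entropies[-1] == pytest.approx(1.0, abs=1e-10)
        assert concurrences[-1] == pytest.approx(1.0, abs=1e-10)
        # both increase monotonically along the sweep
        assert np.all(np.diff(entropies) > -1e-12)
        assert np.all(np.diff(concurrences) > -1e-12)


class TestEntanglementScore:
    def _columns(self, cols):
        return np.column_stack(cols).astype(float)

    def test_all_zero_columns_score_zero(self):
        spec = CircuitSpec(2, 1, "CNOT", trainable_params=np.zeros((1, 2)))
        with pytest.warns(UserWarning, match="constant"):
            score = entanglement_score(
                self._columns([np.zeros(8), np.zeros(8)]), (0, 1), spec
            )
        assert score == 0.0

    @pytest.mark.parametrize("measure", ["entropy", "concurrence"])
    def test_score_bounded(self, rng, measure):
        values = rng.normal(size=(40, 3))
        score = entanglement_score(values, (0, 2), CircuitSpec(param_seed=3), measure=measure)
        assert 0.0 <= score <= 1.0

    def test_four_row_closed_form(self):
        # rows scale to angles (pi/2, 0) Bell-like and (0, 0) trivial
        spec = CircuitSpec(2, 1, "CNOT", trainable_params=np.zeros((1, 2)))
        col_i = np.array([0.5, 0.0, 1.0, 0.5])  # minmax -> 0.5,0,1,0.5
        col_j = np.array([0.0, 0.0, 1.0, 0.0])
        score = entanglement_score(
            self._columns([col_i, col_j]), (0, 1), spec, batch=4, sample_seed=0
        )
        # per-row: RY(pi v_i) on q0, RY(pi v_j) on q1, then CNOT.
        # entropy of q0's reduction depends only on v_j through the CNOT:
        # rows -> angles (pi/2,0): Bell -> 1 bit; (0,0): |00> -> 0;
        # (pi,pi): RYs then CNOT is still a product in the Schmidt basis -> 0;
        # (pi/2,0) again -> 1. mean = 0.5
        assert score == pytest.approx(0.5, abs=1e-10)

    def test_symmetric_in_pair_order(self, rng):
        values = rng.normal(size=(30, 4))
        spec = CircuitSpec(param_seed=5)
        s_ij = entanglement_score(values, (1, 3), spec, sample_seed=2)
        s_ji = entanglement_score(values, (3, 1), spec, sample_seed=2)
        # pair order is canonicalized, so the directed CNOT cannot break symmetry
        assert s_ij == pytest.approx(s_ji, abs=1e-12)
        assert 0 <= s_ji <= 1

    def test_matches_general_simulator_row_by_row(self, rng):
        values = rng.normal(size=(12, 2))
        spec = CircuitSpec(2, 3, "CZ", param_seed=11)
        score = entanglement_score(values, (0, 1), spec, batch=12, sample_seed=0)
        # independent recomputation through the generic statevector path
        lo, hi = values.min(axis=0), values.max(axis=0)
        angles = np.pi * (values - lo) / (hi - lo)
        per_row = []
        for a0, a1 in angles:
            state = reuploading_circuit(spec, [a0, a1])
            rho = density_and_partial_trace(state, [0])
            per_row.append(von_neumann_entropy(rho))
        assert score == pytest.approx(np.mean(per_row), abs=1e-10)

    def test_self_pair_rejected(self, rng):
        with pytest.raises(ValueError):
            entanglement_score(rng.normal(size=(10, 3)), (1, 1))


class TestScoreAllEdges:
    def test_empty_graph_empty_scores(self, rng):
        corr = CorrelationMatrix(np.eye(3))
        graph = build_adjacency(corr, tau=0.5)
        scores = score_all_edges(rng.normal(size=(20, 3)), graph)
        assert len(scores) == 0

    def test_single_edge_single_score(self, rng):
        corr = CorrelationMatrix(np.array([[1.0, 0.9], [0.9, 1.0]]))
        graph = build_adjacency(corr, tau=0.5)
        scores = score_all_edges(rng.normal(size=(20, 2)), graph)
        assert len(scores) == 1 and (0, 1) in scores

    def test_matches_pairwise_loop(self, rng):
        values = rng.normal(size=(30, 5))
        values[:, 1] = values[:, 0] + 0.1 * rng.normal(size=30)
        values[:, 3] = -values[:, 2] + 0.1 * rng.normal(size=30)
        from dgqfs.feature_graph import pearson_correlation

        graph = build_adjacency(pearson_correlation(values), tau=0.5)
        spec = CircuitSpec(param_seed=4)
        scores = score_all_edges(values, graph, spec, batch=16, sample_seed=9)
        assert len(scores) >= 2
        for (i, j), s in scores.items():
            direct = entanglement_score(values, (i, j), spec, batch=16, sample_seed=9)
            assert s == pytest.approx(direct, abs=1e-12)

    def test_block_mode_scores_bounded(self, rng):
        values = rng.normal(size=(24, 6))
        for j in range(1, 6):
            values[:, j] = values[:, 0] + 0.2 * rng.normal(size=24)
        from dgqfs.feature_graph import pearson_correlation

        graph = build_adjacency(pearson_correlation(values), tau=0.5)
        spec = CircuitSpec(n_qubits=6, n_layers=2, param_seed=1)
        scores = score_all_edges(values, graph, spec, batch=8, sample_seed=0, mode="block")
        assert len(scores) == len(graph.edges())
        assert all(0.0 <= s <= 1.0 for _, s in scores.items())
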