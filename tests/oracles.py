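"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's reshape/einsum simulator: circuits are
evaluated as explicit 2^n x 2^n matrix products so the two routes share no
code.
"""

import numpy as np


def ry_mat(theta):
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    return np.array([[c, -s], [s, c]], dtype=complex)


def kron_all(mats):
    out = np.eye(1, dtype=complex)
    for m in mats:
        out = np.kron(out, m)
    return out


def cnot_chain_matrix(n):
    """Full unitary for the chain CNOT q0->q1, ..., q(n-2)->q(n-1)."""
    dim = 2**n
    out = np.eye(dim, dtype=complex)
    for ctrl in range(n - 1):
        tgt = ctrl + 1
        gate = np.zeros((dim, dim), dtype=complex)
        for idx in range(dim):
            bits = [(idx >> (n - 1 - q)) & 1 for q in range(n)]
            if bits[ctrl] == 1:
                bits[tgt] ^= 1
            jdx = sum(b << (n - 1 - q) for q, b in enumerate(bits))
            gate[jdx, idx] = 1.0
        out = gate @ out
    return out


def cz_chain_matrix(n):
    dim = 2**n
    out = np.eye(dim, dtype=complex)
    for ctrl in range(n - 1):
        tgt = ctrl + 1
        gate = np.eye(dim, dtype=complex)
        for idx in range(dim):
            bits = [(idx >> (n - 1 - q)) & 1 for q in range(n)]
            if bits[ctrl] == 1 and bits[tgt] == 1:
                gate[idx, idx] = -1.0
        out = gate @ out
    return out


def oracle_circuit(spec, data_angles):
    """Gate-by-gate matrix-product evaluation of a re-uploading circuit."""
    n = spec.n_qubits
    params = spec.resolved_params()
    ent = cnot_chain_matrix(n) if spec.entangler == "CNOT" else cz_chain_matrix(n)
    psi = np.zeros(2**n, dtype=complex)
    psi[0] = 1.0
    for layer in range(spec.n_layers):
        psi = kron_all([ry_mat(a) for a in data_angles]) @ psi
        psi = kron_all([ry_mat(a) for a in params[layer]]) @ psi
        if n >= 2:
            psi = ent @ psi
    return psi
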