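"""Shared fixtures and independent oracles.

The oracles here deliberately take different computational routes from the
package code they check: operator matrices are built by Kronecker products
(not the mask-based Pauli action), and fermionic operators are applied
directly to occupation bit strings with explicit parity counting (not via
the Jordan-Wigner Pauli algebra).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from vqebench.fixtures import fixture_integrals

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from vqebench.hamiltonian import random_integral_set
from vqebench.operators import FermionOperator, PauliString, QubitHamiltonian

_PAULI_MATS = {
    "I": np.eye(2, dtype=complex),
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
}


def pauli_matrix_kron(ps: PauliString, n_qubits: int) -> np.ndarray:
    """Pauli-string matrix by explicit Kronecker products, qubit 0 leftmost."""
    labels = dict(ps.factors)
    mat = np.array([[1.0 + 0j]])
    for q in range(n_qubits):
        mat = np.kron(mat, _PAULI_MATS[labels.get(q, "I")])
    return mat


def hamiltonian_matrix_kron(h: QubitHamiltonian) -> np.ndarray:
    """Qubit-Hamiltonian matrix by Kronecker products."""
    dim = 2**h.n_qubits
    mat = np.zeros((dim, dim), dtype=complex)
    for ps, coeff in h.terms.items():
        mat += coeff * pauli_matrix_kron(ps, h.n_qubits)
    return mat


def fermion_matrix(op: FermionOperator, n_spin_orbitals: int) -> np.ndarray:
    """Occupation-number-basis matrix of a fermionic operator.

    Basis index convention matches the simulator: the occupation of spin
    orbital p is bit ``n-1-p`` of the index.  A ladder operator acting on
    orbital p picks up (-1)^(number of occupied orbitals below p) — plain
    second quantization, no Pauli algebra involved.
    """
    n = n_spin_orbitals
    dim = 2**n
    mat = np.zeros((dim, dim), dtype=complex)

    def bit(state: int, p: int) -> int:
        return (state >> (n - 1 - p)) & 1

    def parity(state: int, p: int) -> int:
        count = sum(bit(state, q) for q in range(p))
        return -1 if count & 1 else 1

    for ops, coeff in op.terms.items():
        for ket in range(dim):
            state, amp = ket, complex(coeff)
            for index, creation in reversed(ops):
                occupied = bit(state, index)
                if creation and occupied or (not creation and not occupied):
                    amp = 0.0
                    break
                amp *= parity(state, index)
                state ^= 1 << (n - 1 - index)
            if amp != 0.0:
                mat[state, ket] += amp
    return mat


@pytest.fixture(scope="session")
def h2_integrals():
    return fixture_integrals("h2")


@pytest.fixture(scope="session")
def small_random_integrals():
    """A deterministic grid of small random integral sets."""
    return {
        "2o2e": random_integral_set(2, 2, seed=101),
        "3o2e": random_integral_set(3, 2, seed=202),
        "3o4e": random_integral_set(3, 4, seed=303),
        "4o4e": random_integral_set(4, 4, seed=404),
    }
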