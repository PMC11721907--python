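"""Statevector conventions, gate identities, expectations and diagonalization."""

import numpy as np
import pytest
import scipy.linalg

from conftest import hamiltonian_matrix_kron
from vqebench.errors import ArityError, CapacityError
from vqebench.operators import PauliString, QubitHamiltonian
from vqebench.simulator import (
    Gate,
    apply_circuit,
    apply_gate,
    exact_spectrum,
    expectation,
    ground_energy_in_sector,
    hamiltonian_matrix,
    init_state,
    sector_indices,
)


def random_hamiltonian(n_qubits: int, n_terms: int, seed: int) -> QubitHamiltonian:
    rng = np.random.default_rng(seed)
    terms = {}
    for _ in range(n_terms):
        factors = tuple(
            (int(q), "XYZ"[rng.integers(3)])
            for q in rng.choice(n_qubits, size=rng.integers(1, n_qubits + 1),
                                replace=False)
        )
        terms[PauliString(factors)] = float(rng.normal())
    return QubitHamiltonian(n_qubits, terms)


def random_state(n_qubits: int, seed: int):
    rng = np.random.default_rng(seed)
    amp = rng.normal(size=2**n_qubits) + 1j * rng.normal(size=2**n_qubits)
    from vqebench.simulator import Statevector

    return Statevector(n_qubits, amp / np.linalg.norm(amp))


class TestInitState:
    def test_default_is_all_zero(self):
        s = init_state(2)
        assert s.amplitudes[0] == 1.0 and np.count_nonzero(s.amplitudes) == 1

    def test_qubit0_is_most_significant_bit(self):
        s = init_state(2, [1, 0])
        assert s.amplitudes[2] == 1.0

    def test_all_ones_is_last_index(self):
        s = init_state(3, [1, 1, 1])
        assert s.amplitudes[7] == 1.0

    def test_capacity_cap(self):
        with pytest.raises(CapacityError):
            init_state(25)


class TestGates:
    def test_hadamard_on_zero(self):
        s = apply_gate(init_state(1), Gate("H", (0,)))
        np.testing.assert_allclose(s.amplitudes, [1 / np.sqrt(2)] * 2)

    def test_cnot_creates_bell_state(self):
        s = apply_circuit(init_state(2), [Gate("H", (0,)), Gate("CNOT", (0, 1))])
        np.testing.assert_allclose(
            s.amplitudes, [1 / np.sqrt(2), 0, 0, 1 / np.sqrt(2)], atol=1e-12
        )

    def test_rx_zero_is_identity_and_ry_pi_flips(self):
        s = apply_gate(init_state(1), Gate("RX", (0,), angle=0.0))
        np.testing.assert_allclose(s.amplitudes, [1, 0])
        s = apply_gate(init_state(1), Gate("RY", (0,), angle=np.pi))
        assert abs(s.amplitudes[1]) == pytest.approx(1.0)

    @pytest.mark.parametrize("gates", [
        [Gate("H", (0,))] * 2,
        [Gate("CNOT", (0, 2))] * 2,
        [Gate("RX", (1,), angle=0.7), Gate("RX", (1,), angle=-0.7)],
        [Gate("RZ", (2,), angle=1.3), Gate("RZ", (2,), angle=-1.3)],
    ])
    def test_involution_identities(self, gates):
        s0 = random_state(3, seed=5)
        s1 = apply_circuit(s0, gates)
        np.testing.assert_allclose(s1.amplitudes, s0.amplitudes, atol=1e-10)

    def test_norm_preserved_over_long_random_circuit(self):
        rng = np.random.default_rng(12)
        s = random_state(4, seed=0)
        for _ in range(1000):
            kind = rng.choice(["H", "X", "RX", "RY", "RZ", "CNOT"])
            if kind == "CNOT":
                q = tuple(rng.choice(4, size=2, replace=False).astype(int))
                g = Gate("CNOT", q)
            else:
                g = Gate(kind, (int(rng.integers(4)),), angle=float(rng.normal()))
            s = apply_gate(s, g)
        assert s.norm == pytest.approx(1.0, abs=1e-9)

    def test_operations_are_pure(self):
        s0 = init_state(2)
        before = s0.amplitudes.copy()
        apply_gate(s0, Gate("X", (0,)))
        np.testing.assert_array_equal(s0.amplitudes, before)


class TestExpectation:
    def test_z_on_zero_state_is_plus_one(self):
        s = init_state(3)
        for q in range(3):
            h = QubitHamiltonian(3, {PauliString(((q, "Z"),)): 1.0})
            assert expectation(s, h) == pytest.approx(1.0)

    def test_bell_state_correlations(self):
        bell = apply_circuit(init_state(2), [Gate("H", (0,)), Gate("CNOT", (0, 1))])
        zz = QubitHamiltonian(2, {PauliString(((0, "Z"), (1, "Z"))): 1.0})
        z0 = QubitHamiltonian(2, {PauliString(((0, "Z"),)): 1.0})
        assert expectation(bell, zz) == pytest.approx(1.0)
        assert expectation(bell, z0) == pytest.approx(0.0, abs=1e-12)

    def test_identity_term_and_linearity(self):
        s = random_state(3, seed=3)
        h1 = random_hamiltonian(3, 5, seed=4)
        const = QubitHamiltonian(3, {PauliString(): 2.5})
        assert expectation(s, const) == pytest.approx(2.5)
        scaled = QubitHamiltonian(3, {k: 3.0 * v for k, v in h1.terms.items()})
        assert expectation(s, scaled) == pytest.approx(3.0 * expectation(s, h1))

    def test_random_6q_matches_dense_quadratic_form(self):
        s = random_state(6, seed=7)
        h = random_hamiltonian(6, 30, seed=8)
        mat = hamiltonian_matrix_kron(h)
        direct = np.real(np.vdot(s.amplitudes, mat @ s.amplitudes))
        assert expectation(s, h) == pytest.approx(direct, abs=1e-10)

    def test_qubit_count_mismatch(self):
        with pytest.raises(ArityError):
            expectation(init_state(2), random_hamiltonian(3, 2, seed=0))


class TestExactSpectrum:
    def test_single_z(self):
        h = QubitHamiltonian(1, {PauliString(((0, "Z"),)): 1.0})
        assert exact_spectrum(h, k=2) == pytest.approx([-1.0, 1.0])

    def test_shifted_two_qubit_sum(self):
        h = QubitHamiltonian(2, {
            PauliString(((0, "Z"),)): 0.5,
            PauliString(((1, "Z"),)): 0.5,
            PauliString(): 2.0,
        })
        assert exact_spectrum(h, k=1) == pytest.approx([1.0])

    def test_random_6q_matches_kron_eigensolver(self):
        h = random_hamiltonian(6, 25, seed=9)
        ours = exact_spectrum(h, k=10)
        ref = np.sort(scipy.linalg.eigvalsh(hamiltonian_matrix_kron(h)))[:10]
        np.testing.assert_allclose(ours, ref, atol=1e-9)

    def test_mask_matrix_equals_kron_matrix(self):
        h = random_hamiltonian(5, 15, seed=10)
        np.testing.assert_allclose(
            hamiltonian_matrix(h), hamiltonian_matrix_kron(h), atol=1e-12
        )

    def test_capacity_error_over_cap(self):
        h = QubitHamiltonian(17, {PauliString(((16, "Z"),)): 1.0})
        with pytest.raises(CapacityError):
            exact_spectrum(h, k=1, cap=16)

    def test_variational_bound_over_random_states(self):
        h = random_hamiltonian(4, 12, seed=11)
        ground = exact_spectrum(h, k=1)[0]
        for seed in range(100):
            assert expectation(random_state(4, seed), h) >= ground - 1e-9


class TestSectorRestriction:
    def test_sector_sizes(self):
        assert len(sector_indices(4, 2)) == 6
        assert len(sector_indices(4, 2, n_alpha=1)) == 4

    def test_sector_ground_bounded_by_global_ground(self):
        h = random_hamiltonian(4, 12, seed=13)
        global_ground = exact_spectrum(h, k=1)[0]
        assert ground_energy_in_sector(h, 2) >= global_ground - 1e-9
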