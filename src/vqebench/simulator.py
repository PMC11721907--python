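"""Dense statevector simulation of parameterized circuits and Pauli-sum observables.

Conventions
-----------
* Qubit 0 is the **most significant** bit of the amplitude index: on two
  qubits the basis order is |00>, |01>, |10>, |11> and setting qubit 0 moves
  the amplitude to index 2.  A dedicated convention test pins this down,
  since it is the classic source of silent disagreements between simulators.
* All operations are pure: they return new :class:`Statevector` objects and
  never mutate their inputs.
* Expectation values are exact (no sampling noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .errors import ArityError, CapacityError, GateError
from .operators import PauliString, QubitHamiltonian

__all__ = [
    "Statevector",
    "Gate",
    "init_state",
    "apply_gate",
    "apply_circuit",
    "expectation",
    "exact_spectrum",
    "hamiltonian_matrix",
    "apply_pauli",
    "sector_indices",
    "sector_matrix",
    "ground_energy_in_sector",
]

#: Largest register the dense simulator will allocate by default.
DEFAULT_QUBIT_CAP = 20

#: Largest register diagonalized with a dense solver; above this (up to the
#: requested cap) a sparse Lanczos solver is used.
DENSE_DIAG_LIMIT = 12

ROTATION_KINDS = ("RX", "RY", "RZ")
GATE_KINDS = ("H", "X", "RX", "RY", "RZ", "CNOT")

_H = np.array([[1.0, 1.0], [1.0, -1.0]]) / np.sqrt(2.0)
_X = np.array([[0.0, 1.0], [1.0, 0.0]])


@dataclass(frozen=True)
class Statevector:
    """An ``n_qubits`` register as 2**n complex amplitudes."""

    n_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self):
        amp = np.asarray(self.amplitudes, dtype=complex)
        if amp.shape != (2**self.n_qubits,):
            raise ArityError(
                f"expected {2**self.n_qubits} amplitudes, got shape {amp.shape}"
            )
        object.__setattr__(self, "amplitudes", amp)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def check_normalized(self, tol: float = 1e-10) -> None:
        if abs(self.norm - 1.0) > tol:
            raise ValueError(f"state norm {self.norm} deviates from 1 by more than {tol}")


@dataclass(frozen=True)
class Gate:
    """One circuit element.

    ``qubits`` is ``(target,)`` for single-qubit gates and
    ``(control, target)`` for CNOT.  Rotation gates carry either a fixed
    ``angle`` or a trainable ``parameter_slot``; a slotted gate's bound angle
    is ``scale * theta[slot] + angle``, which lets exponentiated-Pauli
    constructions reuse one parameter across several rotations.
    """

    kind: str
    qubits: tuple[int, ...]
    angle: float = 0.0
    parameter_slot: Optional[int] = None
    scale: float = 1.0

    def __post_init__(self):
        if self.kind not in GATE_KINDS:
            raise GateError(f"unknown gate kind {self.kind!r}")
        expected = 2 if self.kind == "CNOT" else 1
        if len(self.qubits) != expected or len(set(self.qubits)) != expected:
            raise GateError(f"{self.kind} needs {expected} distinct qubits, got {self.qubits}")
        if any(q < 0 for q in self.qubits):
            raise GateError(f"negative qubit index in {self.qubits}")
        if not np.isfinite(self.angle) or not np.isfinite(self.scale):
            raise GateError("gate angle and scale must be finite")
        if self.parameter_slot is not None and self.kind not in ROTATION_KINDS:
            raise GateError(f"gate kind {self.kind} cannot carry a parameter slot")

    @property
    def is_parameterized(self) -> bool:
        return self.parameter_slot is not None

    def bound_angle(self, theta: Optional[Sequence[float]] = None) -> float:
        if self.parameter_slot is None:
            return self.angle
        if theta is None:
            raise ArityError(f"gate {self} needs a parameter vector")
        return self.scale * float(theta[self.parameter_slot]) + self.angle


def _rotation_matrix(kind: str, angle: float) -> np.ndarray:
    c, s = np.cos(angle / 2.0), np.sin(angle / 2.0)
    if kind == "RX":
        return np.array([[c, -1j * s], [-1j * s, c]])
    if kind == "RY":
        return np.array([[c, -s], [s, c]])
    if kind == "RZ":
        return np.array([[c - 1j * s, 0.0], [0.0, c + 1j * s]])
    raise GateError(f"{kind} is not a rotation gate")


def gate_matrix(gate: Gate, theta: Optional[Sequence[float]] = None) -> np.ndarray:
    """The 2x2 (or 4x4 for CNOT) unitary of ``gate``."""
    if gate.kind == "H":
        return _H.astype(complex)
    if gate.kind == "X":
        return _X.astype(complex)
    if gate.kind == "CNOT":
        m = np.eye(4, dtype=complex)
        m[2:, 2:] = _X
        return m
    return _rotation_matrix(gate.kind, gate.bound_angle(theta))


def init_state(n_qubits: int, occupation_bits: Optional[Sequence[int]] = None,
               cap: int = DEFAULT_QUBIT_CAP) -> Statevector:
    """Prepare |0...0> or the computational basis state given by ``occupation_bits``."""
    if n_qubits < 1:
        raise ArityError("need at least one qubit")
    if n_qubits > cap:
        raise CapacityError(f"{n_qubits} qubits exceed the configured cap of {cap}")
    amp = np.zeros(2**n_qubits, dtype=complex)
    index = 0
    if occupation_bits is not None:
        if len(occupation_bits) != n_qubits:
            raise ArityError(
                f"occupation list has {len(occupation_bits)} bits for {n_qubits} qubits"
            )
        for q, bit in enumerate(occupation_bits):
            if bit not in (0, 1):
                raise ValueError(f"occupation bits must be 0/1, got {bit!r}")
            if bit:
                index |= 1 << (n_qubits - 1 - q)
    amp[index] = 1.0
    return Statevector(n_qubits, amp)


def _apply_single(amp: np.ndarray, n: int, q: int, m: np.ndarray) -> np.ndarray:
    tensor = amp.reshape((2,) * n)
    tensor = np.moveaxis(tensor, q, 0)
    out = np.tensordot(m, tensor, axes=([1], [0]))
    return np.moveaxis(out, 0, q).reshape(-1)


def _apply_cnot(amp: np.ndarray, n: int, control: int, target: int) -> np.ndarray:
    tensor = amp.reshape((2,) * n).copy()
    sl: list = [slice(None)] * n
    sl[control] = 1
    sub = tensor[tuple(sl)]
    tensor[tuple(sl)] = np.flip(sub, axis=target if target < control else target - 1)
    return tensor.reshape(-1)


def apply_gate(state: Statevector, gate: Gate,
               theta: Optional[Sequence[float]] = None) -> Statevector:
    """Apply a single gate, returning a new state."""
    n = state.n_qubits
    if any(q >= n for q in gate.qubits):
        raise GateError(f"gate {gate.kind} on {gate.qubits} exceeds {n} qubits")
    if gate.kind == "CNOT":
        control, target = gate.qubits
        amp = _apply_cnot(state.amplitudes, n, control, target)
    else:
        amp = _apply_single(state.amplitudes, n, gate.qubits[0], gate_matrix(gate, theta))
    return Statevector(n, amp)


def apply_circuit(state: Statevector, gates: Sequence[Gate],
                  theta: Optional[Sequence[float]] = None) -> Statevector:
    """Apply an ordered gate list."""
    amp = state.amplitudes
    n = state.n_qubits
    for gate in gates:
        if any(q >= n for q in gate.qubits):
            raise GateError(f"gate {gate.kind} on {gate.qubits} exceeds {n} qubits")
        if gate.kind == "CNOT":
            amp = _apply_cnot(amp, n, *gate.qubits)
        else:
            amp = _apply_single(amp, n, gate.qubits[0], gate_matrix(gate, theta))
    return Statevector(n, amp)


def _pauli_action(ps: PauliString, n: int):
    """Index permutation and phase array of a Pauli string: P|i> = phase[i] |i ^ flip>."""
    mx, my, mz = ps.masks(n)
    idx = np.arange(2**n)
    flip = mx | my
    phase = np.ones(2**n, dtype=complex)
    # Y = i.X.Z, so Y bits join the Z-parity mask and contribute a global i each
    zy = mz | my
    if zy:
        parity = np.zeros(2**n, dtype=np.int64)
        bits = idx & zy
        while zy:
            parity ^= bits & 1
            bits >>= 1
            zy >>= 1
        phase = np.where(parity, -1.0, 1.0).astype(complex)
    n_y = bin(my).count("1")
    if n_y:
        phase = phase * (1j ** (n_y & 3))
    return idx ^ flip, phase


def apply_pauli(state: Statevector, ps: PauliString) -> Statevector:
    """Apply a Pauli string to a state."""
    n = state.n_qubits
    if ps.max_qubit >= n:
        raise ArityError(f"Pauli string {ps} exceeds {n} qubits")
    perm, phase = _pauli_action(ps, n)
    amp = np.zeros_like(state.amplitudes)
    amp[perm] = phase * state.amplitudes
    return Statevector(n, amp)


def apply_hamiltonian(state: Statevector, h: QubitHamiltonian) -> Statevector:
    """H|psi> as a dense vector (not normalized)."""
    if state.n_qubits != h.n_qubits:
        raise ArityError(
            f"state has {state.n_qubits} qubits, Hamiltonian {h.n_qubits}"
        )
    out = np.zeros_like(state.amplitudes)
    for ps, coeff in h.terms.items():
        perm, phase = _pauli_action(ps, h.n_qubits)
        out[perm] += coeff * phase * state.amplitudes
    return Statevector(state.n_qubits, out)


def expectation(state: Statevector, h: QubitHamiltonian) -> float:
    """<psi|H|psi> for a Pauli-sum Hamiltonian, in Hartree.

    The imaginary residue must stay below 1e-9 (it does for Hermitian sums);
    it is checked and discarded.
    """
    if state.n_qubits != h.n_qubits:
        raise ArityError(
            f"state has {state.n_qubits} qubits, Hamiltonian {h.n_qubits}"
        )
    psi = state.amplitudes
    value = 0.0 + 0.0j
    for ps, coeff in h.terms.items():
        perm, phase = _pauli_action(ps, h.n_qubits)
        value += coeff * np.vdot(psi[perm], phase * psi)
    if abs(value.imag) > 1e-9:
        raise ValueError(f"expectation has imaginary residue {value.imag:.3e}")
    return float(value.real)


def hamiltonian_matrix(h: QubitHamiltonian, sparse: bool = False):
    """The explicit (2^n, 2^n) Hermitian matrix of a Pauli-sum Hamiltonian."""
    n = h.n_qubits
    dim = 2**n
    idx = np.arange(dim)
    if sparse:
        mat = scipy.sparse.csr_matrix((dim, dim), dtype=complex)
        for ps, coeff in h.terms.items():
            perm, phase = _pauli_action(ps, n)
            mat = mat + scipy.sparse.csr_matrix(
                (coeff * phase, (perm, idx)), shape=(dim, dim)
            )
        return mat
    mat = np.zeros((dim, dim), dtype=complex)
    for ps, coeff in h.terms.items():
        perm, phase = _pauli_action(ps, n)
        mat[perm, idx] += coeff * phase
    return mat


def sector_indices(n_qubits: int, n_particles: int,
                   n_alpha: Optional[int] = None) -> list[int]:
    """Basis indices of the fixed-particle-number (and optionally fixed-Sz) sector.

    Occupation of qubit q is bit ``n-1-q`` of the index; with the blocked
    spin layout the first ``n/2`` qubits are the alpha spin orbitals, so
    ``n_alpha`` restricts to one Sz sector.
    """
    half_mask = ((1 << (n_qubits // 2)) - 1) << (n_qubits - n_qubits // 2)
    out = []
    for i in range(2**n_qubits):
        if bin(i).count("1") != n_particles:
            continue
        if n_alpha is not None and bin(i & half_mask).count("1") != n_alpha:
            continue
        out.append(i)
    return out


def sector_matrix(h: QubitHamiltonian, indices: Sequence[int]) -> np.ndarray:
    """The Hamiltonian block over the given basis indices, without 2^n storage."""
    n = h.n_qubits
    pos = {i: a for a, i in enumerate(indices)}
    mat = np.zeros((len(indices), len(indices)), dtype=complex)
    for ps, coeff in h.terms.items():
        mx, my, mz = ps.masks(n)
        flip = mx | my
        zy = mz | my
        yphase = 1j ** (bin(my).count("1") & 3)
        for i in indices:
            j = i ^ flip
            b = pos.get(j)
            if b is None:
                continue
            sign = -1.0 if bin(i & zy).count("1") & 1 else 1.0
            mat[b, pos[i]] += coeff * sign * yphase
    return mat


def ground_energy_in_sector(h: QubitHamiltonian, n_particles: int,
                            n_alpha: Optional[int] = None) -> float:
    """Lowest eigenvalue of the Hamiltonian restricted to one particle sector."""
    idx = sector_indices(h.n_qubits, n_particles, n_alpha)
    if not idx:
        raise ValueError(
            f"empty sector: {n_particles} particles on {h.n_qubits} qubits"
        )
    mat = sector_matrix(h, idx)
    return float(scipy.linalg.eigvalsh(mat)[0])


def exact_spectrum(h: QubitHamiltonian, k: int = 1,
                   cap: int = 16) -> list[float]:
    """The ``k`` smallest eigenvalues of the Hamiltonian, ascending (Hartree).

    Registers up to :data:`DENSE_DIAG_LIMIT` qubits are diagonalized densely;
    larger ones (up to ``cap``) fall back to a sparse Lanczos solver.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if h.n_qubits > cap:
        raise CapacityError(
            f"{h.n_qubits} qubits exceed the diagonalization cap of {cap}; "
            "raise the cap or use an iterative solver on the sparse matrix"
        )
    dim = 2**h.n_qubits
    k = min(k, dim)
    if h.n_qubits <= DENSE_DIAG_LIMIT or k >= dim - 1:
        eigvals = scipy.linalg.eigvalsh(hamiltonian_matrix(h))
        return [float(v) for v in eigvals[:k]]
    mat = hamiltonian_matrix(h, sparse=True)
    eigvals = scipy.sparse.linalg.eigsh(mat, k=k, which="SA",
                                        return_eigenvectors=False)
    return sorted(float(v) for v in eigvals)
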