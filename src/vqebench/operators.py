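"""Fermionic operators, Pauli strings and the Jordan-Wigner transformation.

The Jordan-Wigner map sends ladder operators on spin orbital ``p`` to Pauli
strings with a Z-parity chain on all lower-indexed qubits::

    a†_p -> (X_p - iY_p)/2 . Z_0 ... Z_{p-1}
    a_p  -> (X_p + iY_p)/2 . Z_0 ... Z_{p-1}

so one qubit encodes the occupation of one spin orbital and the chain carries
the fermionic antisymmetry.  Internally products are tracked in the
symplectic (X-mask, Z-mask) representation, where multiplication is XOR plus
a sign, and converted to X/Y/Z labels only at the end.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass, field

import numpy as np

from .errors import HermiticityError

__all__ = [
    "FermionOperator",
    "PauliString",
    "QubitHamiltonian",
    "jordan_wigner",
    "jordan_wigner_complex",
    "number_operator",
]

#: Pauli coefficients below this magnitude are dropped after term collection.
COEFF_TRUNCATION = 1e-12

# A fermionic term is an ordered product of ladder operators, encoded as a
# tuple of (spin-orbital index, is_creation) pairs; () is the identity.
LadderTerm = tuple[tuple[int, bool], ...]


@dataclass
class FermionOperator:
    """A real-coefficient linear combination of ladder-operator products."""

    terms: dict[LadderTerm, float] = field(default_factory=dict)

    def __post_init__(self):
        for ops, coeff in self.terms.items():
            if not np.isfinite(coeff):
                raise ValueError(f"non-finite coefficient for term {ops}")
            for (i1, c1), (i2, c2) in zip(ops, ops[1:]):
                if i1 == i2 and c1 == c2:
                    raise ValueError(
                        f"term {ops} repeats {'creation' if c1 else 'annihilation'} "
                        f"on index {i1}; the product is identically zero"
                    )

    def add_term(self, ops: LadderTerm, coeff: float) -> None:
        self.terms[ops] = self.terms.get(ops, 0.0) + coeff

    @property
    def max_index(self) -> int:
        return max((i for ops in self.terms for i, _ in ops), default=-1)

    def hermitian_conjugate(self) -> "FermionOperator":
        out = FermionOperator()
        for ops, coeff in self.terms.items():
            conj = tuple((i, not c) for i, c in reversed(ops))
            out.add_term(conj, coeff)
        return out

    def __add__(self, other: "FermionOperator") -> "FermionOperator":
        out = FermionOperator(dict(self.terms))
        for ops, coeff in other.terms.items():
            out.add_term(ops, coeff)
        return out

    def __sub__(self, other: "FermionOperator") -> "FermionOperator":
        out = FermionOperator(dict(self.terms))
        for ops, coeff in other.terms.items():
            out.add_term(ops, -coeff)
        return out


@dataclass(frozen=True)
class PauliString:
    """A tensor product of X/Y/Z factors on distinct qubits; identity elsewhere."""

    factors: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        seen = set()
        for q, label in self.factors:
            if q < 0:
                raise ValueError(f"negative qubit index {q}")
            if label not in ("X", "Y", "Z"):
                raise ValueError(f"invalid Pauli label {label!r}")
            if q in seen:
                raise ValueError(f"duplicate qubit index {q}")
            seen.add(q)
        object.__setattr__(self, "factors", tuple(sorted(self.factors)))

    @property
    def weight(self) -> int:
        return len(self.factors)

    @property
    def max_qubit(self) -> int:
        return max((q for q, _ in self.factors), default=-1)

    def masks(self, n_qubits: int) -> tuple[int, int, int]:
        """Bit masks (x, y, z) with qubit 0 at the most significant bit."""
        mx = my = mz = 0
        for q, label in self.factors:
            bit = 1 << (n_qubits - 1 - q)
            if label == "X":
                mx |= bit
            elif label == "Y":
                my |= bit
            else:
                mz |= bit
        return mx, my, mz

    def __str__(self) -> str:
        return " ".join(f"{label}{q}" for q, label in self.factors) or "I"


@dataclass
class QubitHamiltonian:
    """A Hermitian weighted sum of Pauli strings on ``n_qubits`` qubits (Hartree)."""

    n_qubits: int
    terms: dict[PauliString, float] = field(default_factory=dict)

    def __post_init__(self):
        for ps, coeff in self.terms.items():
            if not np.isfinite(coeff):
                raise ValueError(f"non-finite coefficient for {ps}")
            if ps.max_qubit >= self.n_qubits:
                raise ValueError(
                    f"term {ps} touches qubit {ps.max_qubit} but the Hamiltonian "
                    f"has only {self.n_qubits} qubits"
                )

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def constant(self) -> float:
        return self.terms.get(PauliString(), 0.0)

    def __str__(self) -> str:
        parts = [f"{coeff:+.10g} {ps}" for ps, coeff in sorted(
            self.terms.items(), key=lambda kv: str(kv[0]))]
        return "\n".join(parts)


# ---------------------------------------------------------------------------
# symplectic Pauli algebra: a term is W(x, z) = prod_q X_q^{x_q} Z_q^{z_q};
# W(x1,z1).W(x2,z2) = (-1)^{|z1 & x2|} W(x1^x2, z1^z2).
# ---------------------------------------------------------------------------


def _ladder_w(index: int, creation: bool) -> list[tuple[int, int, complex]]:
    """Jordan-Wigner image of a single ladder operator as W-terms.

    Qubit ``p`` is bit position ``p`` here (ascending, internal only); the
    Z-parity chain covers bits 0..p-1.
    """
    bit = 1 << index
    chain = bit - 1
    sign = -0.5 if creation else 0.5
    # (X_p -/+ iY_p)/2 . Zchain, with Y = iXZ
    return [(bit, chain, 0.5), (bit, chain | bit, -sign)]


def _multiply_w(acc: dict[tuple[int, int], complex],
                factor: list[tuple[int, int, complex]]) -> dict[tuple[int, int], complex]:
    out: dict[tuple[int, int], complex] = {}
    for (x1, z1), c1 in acc.items():
        for x2, z2, c2 in factor:
            sign = -1.0 if (bin(z1 & x2).count("1") & 1) else 1.0
            key = (x1 ^ x2, z1 ^ z2)
            out[key] = out.get(key, 0.0) + c1 * c2 * sign
    return out


def _w_to_pauli(x: int, z: int) -> tuple[PauliString, complex]:
    """Convert W(x, z) to a phase times an X/Y/Z Pauli string."""
    y = x & z
    factors = []
    q = 0
    rest = x | z
    while rest >> q:
        bit = 1 << q
        if y & bit:
            factors.append((q, "Y"))
        elif x & bit:
            factors.append((q, "X"))
        elif z & bit:
            factors.append((q, "Z"))
        q += 1
    phase = (-1j) ** (bin(y).count("1") & 3)
    return PauliString(tuple(factors)), phase


def jordan_wigner_complex(op: FermionOperator) -> dict[PauliString, complex]:
    """Jordan-Wigner map without the Hermiticity requirement.

    Returns the full complex-coefficient Pauli expansion; used both by
    :func:`jordan_wigner` and by anti-Hermitian excitation generators in
    coupled-cluster circuit construction.
    """
    acc_pauli: dict[PauliString, complex] = {}
    for ops, coeff in op.terms.items():
        w_terms: dict[tuple[int, int], complex] = {(0, 0): complex(coeff)}
        for index, creation in ops:
            w_terms = _multiply_w(w_terms, _ladder_w(index, creation))
        for (x, z), c in w_terms.items():
            if c == 0:
                continue
            ps, phase = _w_to_pauli(x, z)
            acc_pauli[ps] = acc_pauli.get(ps, 0.0) + c * phase
    return {ps: c for ps, c in acc_pauli.items() if abs(c) > COEFF_TRUNCATION}


def jordan_wigner(op: FermionOperator, n_spin_orbitals: int) -> QubitHamiltonian:
    """Map a Hermitian fermionic operator to a qubit Hamiltonian.

    Raises :class:`HermiticityError` if the collected Pauli coefficients have
    imaginary residue above 1e-8, which signals a non-Hermitian input.
    """
    if op.max_index >= n_spin_orbitals:
        raise ValueError(
            f"operator touches spin orbital {op.max_index} but only "
            f"{n_spin_orbitals} are declared"
        )
    complex_terms = jordan_wigner_complex(op)
    terms: dict[PauliString, float] = {}
    for ps, c in complex_terms.items():
        if abs(c.imag) > 1e-8:
            raise HermiticityError(
                f"term {ps} has imaginary coefficient {c.imag:.3e}; "
                "the fermionic operator is not Hermitian"
            )
        if abs(c.real) > COEFF_TRUNCATION:
            terms[ps] = c.real
    return QubitHamiltonian(n_qubits=n_spin_orbitals, terms=terms)


def number_operator(n_spin_orbitals: int) -> FermionOperator:
    """Total particle-number operator sum_p a†_p a_p."""
    op = FermionOperator()
    for p in range(n_spin_orbitals):
        op.add_term(((p, True), (p, False)), 1.0)
    return op
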