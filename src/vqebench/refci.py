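"""Classical reference energies by explicit determinant CI.

Full configuration interaction (FCI) diagonalizes the electronic Hamiltonian
over every determinant the orbital space supports — the exact answer within
the basis and the yardstick the variational runs are measured against.  CISD
truncates the expansion to single and double excitations from a closed-shell
reference determinant.

Determinants are occupation bit masks over spin orbitals in the blocked
layout of :mod:`vqebench.hamiltonian` (alpha block first), and matrix
elements come from the Slater-Condon rules.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import ArityError, CapacityError, VQEBenchError
from .hamiltonian import IntegralSet, freeze_core
from .molsys import ActiveSpace

__all__ = [
    "Determinant",
    "hartree_fock_determinant",
    "enumerate_determinants",
    "slater_condon_element",
    "ci_matrix",
    "ci_ground_energy",
    "hf_energy",
]

#: Largest CI matrix dimension the dense solver accepts; C(8,4)^2 = 4900 for
#: an (8e,8o) space fits under it.
CI_DIMENSION_CAP = 8192


@dataclass(frozen=True)
class Determinant:
    """A Slater determinant as an occupation bit list over spin orbitals."""

    occupation: tuple[int, ...]

    def __post_init__(self):
        if any(b not in (0, 1) for b in self.occupation):
            raise ValueError("occupation entries must be 0/1")

    @classmethod
    def from_orbitals(cls, occupied: tuple[int, ...] | list[int],
                      n_spin_orbitals: int) -> "Determinant":
        bits = [0] * n_spin_orbitals
        for p in occupied:
            bits[p] = 1
        return cls(tuple(bits))

    @property
    def n_spin_orbitals(self) -> int:
        return len(self.occupation)

    @property
    def n_electrons(self) -> int:
        return sum(self.occupation)

    @property
    def occupied(self) -> tuple[int, ...]:
        return tuple(p for p, b in enumerate(self.occupation) if b)

    def n_alpha(self, n_orbitals: int) -> int:
        return sum(self.occupation[:n_orbitals])

    def excitation_degree(self, other: "Determinant") -> int:
        return sum(a != b for a, b in zip(self.occupation, other.occupation)) // 2


def hartree_fock_determinant(n_electrons: int, n_spin_orbitals: int) -> Determinant:
    """The closed-shell-style reference: lowest orbitals filled alpha/beta alike."""
    n_orb = n_spin_orbitals // 2
    n_alpha = (n_electrons + 1) // 2
    n_beta = n_electrons - n_alpha
    occ = list(range(n_alpha)) + [n_orb + i for i in range(n_beta)]
    return Determinant.from_orbitals(occ, n_spin_orbitals)


def enumerate_determinants(
    n_electrons: int,
    n_spin_orbitals: int,
    level: str = "FCI",
    reference: Determinant | None = None,
    conserve_sz: bool = True,
) -> list[Determinant]:
    """All determinants of the requested CI level, lexicographic in occupation.

    ``FCI`` enumerates every determinant with the given electron count,
    optionally restricted to the reference's Sz sector; ``CISD`` keeps the
    reference plus determinants within two excitations of it.
    """
    if n_electrons > n_spin_orbitals:
        raise VQEBenchError(
            f"{n_electrons} electrons cannot occupy {n_spin_orbitals} spin orbitals"
        )
    level = level.upper()
    if level not in ("FCI", "CISD"):
        raise ValueError(f"unknown CI level {level!r}")
    if reference is None:
        reference = hartree_fock_determinant(n_electrons, n_spin_orbitals)
    if reference.n_spin_orbitals != n_spin_orbitals or reference.n_electrons != n_electrons:
        raise ArityError("reference determinant inconsistent with problem size")

    n_orb = n_spin_orbitals // 2
    ref_alpha = reference.n_alpha(n_orb)
    out = []
    for occ in itertools.combinations(range(n_spin_orbitals), n_electrons):
        det = Determinant.from_orbitals(occ, n_spin_orbitals)
        if conserve_sz and det.n_alpha(n_orb) != ref_alpha:
            continue
        if level == "CISD" and reference.excitation_degree(det) > 2:
            continue
        out.append(det)
    out.sort(key=lambda d: d.occupation)
    return out


def _spin_orbital_h(p: int, q: int, h: np.ndarray, n_orb: int) -> float:
    if (p < n_orb) != (q < n_orb):
        return 0.0
    return float(h[p % n_orb, q % n_orb])


def _antisym(p: int, q: int, r: int, s: int, g: np.ndarray, n_orb: int) -> float:
    """Antisymmetrized <pq||rs> over spin orbitals from chemists' (ij|kl)."""
    val = 0.0
    # <pq|rs> = (pr|qs) delta(sp,sr) delta(sq,ss)
    if (p < n_orb) == (r < n_orb) and (q < n_orb) == (s < n_orb):
        val += g[p % n_orb, r % n_orb, q % n_orb, s % n_orb]
    if (p < n_orb) == (s < n_orb) and (q < n_orb) == (r < n_orb):
        val -= g[p % n_orb, s % n_orb, q % n_orb, r % n_orb]
    return float(val)


def _annihilate(mask: int, p: int) -> tuple[int, int]:
    """Remove orbital p from the mask, returning (new_mask, sign)."""
    sign = -1 if bin(mask & ((1 << p) - 1)).count("1") & 1 else 1
    return mask & ~(1 << p), sign


def slater_condon_element(d1: Determinant, d2: Determinant,
                          ints: IntegralSet) -> float:
    """<d2|H|d1> by the Slater-Condon rules (electronic part only, Hartree).

    Vanishes identically when the determinants differ in more than two spin
    orbitals; the ``core_energy`` constant is *not* included here.
    """
    if d1.n_spin_orbitals != d2.n_spin_orbitals:
        raise ArityError("determinants have different spin-orbital counts")
    if d1.n_electrons != d2.n_electrons:
        raise ArityError("determinants have different electron counts")
    n_orb = ints.n_orbitals
    if d1.n_spin_orbitals != 2 * n_orb:
        raise ArityError(
            f"determinant over {d1.n_spin_orbitals} spin orbitals does not match "
            f"{n_orb} spatial orbitals"
        )
    h, g = ints.one_body, ints.two_body
    degree = d1.excitation_degree(d2)
    if degree > 2:
        return 0.0

    occ1 = d1.occupied
    if degree == 0:
        val = sum(_spin_orbital_h(p, p, h, n_orb) for p in occ1)
        for p in occ1:
            for q in occ1:
                val += 0.5 * _antisym(p, q, p, q, g, n_orb)
        return float(val)

    mask1 = sum(1 << p for p in occ1)
    mask2 = sum(1 << p for p in d2.occupied)
    holes = sorted(p for p in occ1 if not (mask2 >> p) & 1)
    parts = sorted(p for p in d2.occupied if not (mask1 >> p) & 1)

    if degree == 1:
        p, q = holes[0], parts[0]
        _, s1 = _annihilate(mask1, p)
        _, s2 = _annihilate(mask2, q)
        common = [i for i in occ1 if i != p]
        val = _spin_orbital_h(q, p, h, n_orb)
        for i in common:
            val += _antisym(q, i, p, i, g, n_orb)
        return float(s1 * s2 * val)

    p1, p2 = holes
    q1, q2 = parts
    m, sa = _annihilate(mask1, p2)
    _, sb = _annihilate(m, p1)
    m, sc = _annihilate(mask2, q2)
    _, sd = _annihilate(m, q1)
    return float(sa * sb * sc * sd * _antisym(q1, q2, p1, p2, g, n_orb))


def ci_matrix(dets: list[Determinant], ints: IntegralSet) -> np.ndarray:
    """The real symmetric CI matrix over ``dets`` (electronic part)."""
    dim = len(dets)
    if dim > CI_DIMENSION_CAP:
        raise CapacityError(
            f"CI dimension {dim} exceeds the dense cap of {CI_DIMENSION_CAP}"
        )
    mat = np.zeros((dim, dim))
    for a in range(dim):
        for b in range(a + 1):
            el = slater_condon_element(dets[b], dets[a], ints)
            mat[a, b] = el
            mat[b, a] = el
    return mat


def hf_energy(ints: IntegralSet, n_electrons: int | None = None) -> float:
    """Energy of the single closed-shell reference determinant (plus constant)."""
    ne = ints.n_electrons if n_electrons is None else n_electrons
    det = hartree_fock_determinant(ne, 2 * ints.n_orbitals)
    return slater_condon_element(det, det, ints) + ints.core_energy


def ci_ground_energy(ints: IntegralSet, space: ActiveSpace | None = None,
                     level: str = "FCI", conserve_sz: bool = True) -> float:
    """Lowest CI eigenvalue at the requested level, total energy in Hartree.

    With ``space`` given, the frozen core is folded first and the CI runs in
    the active window; the folded constant is added back so FCI/CISD and the
    qubit-Hamiltonian ground energies live on the same total-energy scale.
    """
    if space is not None:
        ints = freeze_core(ints, space)
    dets = enumerate_determinants(
        ints.n_electrons, 2 * ints.n_orbitals, level=level, conserve_sz=conserve_sz
    )
    mat = ci_matrix(dets, ints)
    eigvals = scipy.linalg.eigvalsh(mat)
    return float(eigvals[0]) + ints.core_energy
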