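"""Molecular integrals, FCIDUMP I/O and active-space Hamiltonian assembly.

The electronic Hamiltonian in second quantization over active spin orbitals is

    H = E_core' + sum_pq h'_pq a†_p a_q
               + 1/2 sum_pqrs,st (pq|rs) a†_{p,s} a†_{r,t} a_{s',t} a_{q,s}

with two-electron integrals stored in chemists' notation (pq|rs) over
spatial orbitals.  Frozen-core folding absorbs the doubly occupied core
orbitals into the constant ``E_core'`` and an effective one-body term.

Spin-orbital layout is **blocked**: for ``n`` active spatial orbitals,
qubits/spin orbitals ``0..n-1`` are the alpha spin orbitals in ascending
orbital order and ``n..2n-1`` their beta partners.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import FCIDUMPError
from .molsys import ActiveSpace, validate_active_space
from .operators import FermionOperator, QubitHamiltonian, jordan_wigner

__all__ = [
    "IntegralSet",
    "read_fcidump",
    "write_fcidump",
    "random_integral_set",
    "freeze_core",
    "build_fermionic_hamiltonian",
    "build_qubit_hamiltonian",
    "spin_orbital_index",
]

SYMMETRY_TOL = 1e-10


@dataclass
class IntegralSet:
    """One- and two-electron integrals over spatial orbitals, in Hartree.

    ``two_body[i, j, k, l]`` is the chemists'-notation integral ``(ij|kl)``
    with its eightfold permutational symmetry; ``core_energy`` carries the
    nuclear repulsion (plus any previously folded core contribution).
    """

    n_orbitals: int
    n_electrons: int
    core_energy: float
    one_body: np.ndarray
    two_body: np.ndarray
    convention: str = "chemist"

    def __post_init__(self):
        n = self.n_orbitals
        self.one_body = np.asarray(self.one_body, dtype=float)
        self.two_body = np.asarray(self.two_body, dtype=float)
        if self.one_body.shape != (n, n):
            raise ValueError(f"one_body shape {self.one_body.shape} != ({n}, {n})")
        if self.two_body.shape != (n, n, n, n):
            raise ValueError(f"two_body shape {self.two_body.shape} != ({n},)*4")
        if self.n_electrons < 0 or self.n_electrons > 2 * n:
            raise ValueError(f"{self.n_electrons} electrons in {n} orbitals")
        self.check_symmetries()

    def check_symmetries(self, tol: float = SYMMETRY_TOL) -> None:
        h, g = self.one_body, self.two_body
        if np.max(np.abs(h - h.T), initial=0.0) > tol:
            raise ValueError("one-body integrals are not symmetric")
        for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
            if np.max(np.abs(g - g.transpose(perm)), initial=0.0) > tol:
                raise ValueError(
                    f"two-body integrals violate permutation symmetry {perm}"
                )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IntegralSet)
            and self.n_orbitals == other.n_orbitals
            and self.n_electrons == other.n_electrons
            and np.isclose(self.core_energy, other.core_energy, atol=1e-12)
            and np.allclose(self.one_body, other.one_body, atol=1e-12)
            and np.allclose(self.two_body, other.two_body, atol=1e-12)
        )


_NAMELIST_KV = re.compile(r"([A-Za-z0-9_]+)\s*=\s*([^,=]+?)(?=\s*(?:,|$|[A-Za-z0-9_]+\s*=))")


def read_fcidump(stream) -> IntegralSet:
    """Parse an FCIDUMP text stream into an :class:`IntegralSet`.

    The header is a Fortran namelist ``&FCI NORB=..., NELEC=..., ... &END``
    (also accepting ``/`` as terminator); records are ``value i j k l`` with
    1-based indices.  ``i=j=k=l=0`` is the core energy, ``k=l=0`` a one-body
    element, anything else a chemists' two-body element ``(ij|kl)``.
    Symmetric completion enforces the full eightfold symmetry.
    """
    text = stream.read()
    upper = text.upper()
    start = upper.find("&FCI")
    if start < 0:
        raise FCIDUMPError("no &FCI namelist header found")
    for terminator in ("&END", "/"):
        end = upper.find(terminator, start + 4)
        if end >= 0:
            break
    else:
        raise FCIDUMPError("unterminated &FCI namelist header")
    header = text[start + 4:end]
    fields = {k.upper(): v.strip() for k, v in _NAMELIST_KV.findall(header)}
    if "NORB" not in fields:
        raise FCIDUMPError("FCIDUMP header missing NORB")
    if "NELEC" not in fields:
        raise FCIDUMPError("FCIDUMP header missing NELEC")
    try:
        n_orb = int(fields["NORB"])
        n_elec = int(fields["NELEC"])
    except ValueError as exc:
        raise FCIDUMPError(f"bad NORB/NELEC values: {fields}") from exc

    core = 0.0
    h = np.zeros((n_orb, n_orb))
    g = np.zeros((n_orb, n_orb, n_orb, n_orb))
    body = text[end + (4 if upper[end:end + 4] == "&END" else 1):]
    for line in body.splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise FCIDUMPError(f"bad integral record: {line!r}")
        value = float(parts[0].replace("D", "E").replace("d", "e"))
        i, j, k, l = (int(p) for p in parts[1:])
        for idx in (i, j, k, l):
            if idx < 0 or idx > n_orb:
                raise FCIDUMPError(f"orbital index {idx} out of range 1..{n_orb}")
        if i == j == k == l == 0:
            core = value
        elif k == 0 and l == 0:
            if i == 0 or j == 0:
                raise FCIDUMPError(f"bad one-body record: {line!r}")
            h[i - 1, j - 1] = value
            h[j - 1, i - 1] = value
        else:
            if 0 in (i, j, k, l):
                raise FCIDUMPError(f"bad two-body record: {line!r}")
            a, b, c, d = i - 1, j - 1, k - 1, l - 1
            for p, q, r, s in _eightfold(a, b, c, d):
                g[p, q, r, s] = value
    return IntegralSet(n_orb, n_elec, core, h, g)


def _eightfold(i, j, k, l):
    return {
        (i, j, k, l), (j, i, k, l), (i, j, l, k), (j, i, l, k),
        (k, l, i, j), (l, k, i, j), (k, l, j, i), (l, k, j, i),
    }


def write_fcidump(ints: IntegralSet, stream, ms2: int = 0,
                  threshold: float = 1e-14) -> None:
    """Write an :class:`IntegralSet` as FCIDUMP text (unique records only)."""
    n = ints.n_orbitals
    stream.write(f"&FCI NORB={n},NELEC={ints.n_electrons},MS2={ms2},\n")
    stream.write(" ORBSYM=" + ",".join(["1"] * n) + ",\n ISYM=1,\n&END\n")
    seen = set()
    for i in range(n):
        for j in range(n):
            for k in range(n):
                for l in range(n):
                    key = frozenset(_eightfold(i, j, k, l))
                    if key in seen:
                        continue
                    seen.add(key)
                    v = ints.two_body[i, j, k, l]
                    if abs(v) > threshold:
                        stream.write(f"{v:23.16e} {i+1:3d} {j+1:3d} {k+1:3d} {l+1:3d}\n")
    for i in range(n):
        for j in range(i + 1):
            v = ints.one_body[i, j]
            if abs(v) > threshold:
                stream.write(f"{v:23.16e} {i+1:3d} {j+1:3d}   0   0\n")
    stream.write(f"{ints.core_energy:23.16e}   0   0   0   0\n")


def random_integral_set(n_orbitals: int, n_electrons: int, seed: int) -> IntegralSet:
    """A deterministic random integral set with realistic HF-like structure.

    One-body: a diagonal of ascending orbital energies (occupied negative,
    virtual positive) plus small symmetric off-diagonal noise.  Two-body:
    dominant positive Coulomb diagonals ``(ii|jj)`` plus weak fully
    8-fold-symmetrized noise.  The result mimics a well-behaved closed-shell
    molecule near its HF minimum, so determinant-CI and VQE runs on it
    behave like the molecular case.
    """
    if n_electrons > 2 * n_orbitals:
        raise ValueError(f"{n_electrons} electrons exceed 2*{n_orbitals} spin orbitals")
    rng = np.random.default_rng(seed)
    n = n_orbitals
    energies = np.sort(rng.uniform(-2.0, 1.5, size=n))
    h = np.diag(energies)
    noise = rng.normal(scale=0.05, size=(n, n))
    h = h + (noise + noise.T) / 2.0

    g = rng.normal(scale=0.02, size=(n, n, n, n))
    for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
        g = (g + g.transpose(perm)) / 2.0
    # re-symmetrize exactly over the full 8-element group
    g = (g + g.transpose(1, 0, 2, 3)) / 2.0
    g = (g + g.transpose(0, 1, 3, 2)) / 2.0
    g = (g + g.transpose(2, 3, 0, 1)) / 2.0
    coulomb = rng.uniform(0.3, 0.7, size=(n, n))
    coulomb = (coulomb + coulomb.T) / 2.0
    for i in range(n):
        for j in range(n):
            g[i, i, j, j] += coulomb[i, j]
    core = float(rng.uniform(0.1, 2.0))
    return IntegralSet(n, n_electrons, core, h, g)


def freeze_core(ints: IntegralSet, space: ActiveSpace) -> IntegralSet:
    """Fold frozen doubly occupied core orbitals into constant + one-body terms.

    Returns an :class:`IntegralSet` over the active orbitals only, with

        E_core' = E_core + 2 sum_i h_ii + sum_ij [2(ii|jj) - (ij|ij)]
        h'_pq   = h_pq + sum_i [2(pq|ii) - (pi|iq)]

    where ``i, j`` run over core and ``p, q`` over active spatial orbitals.
    """
    validate_active_space(space, ints.n_orbitals, ints.n_electrons)
    core = list(range(space.n_core_orbitals))
    active = list(space.active_orbital_indices)
    h, g = ints.one_body, ints.two_body

    e_core = ints.core_energy
    for i in core:
        e_core += 2.0 * h[i, i]
        for j in core:
            e_core += 2.0 * g[i, i, j, j] - g[i, j, j, i]

    n_act = len(active)
    h_eff = np.zeros((n_act, n_act))
    for a, p in enumerate(active):
        for b, q in enumerate(active):
            val = h[p, q]
            for i in core:
                val += 2.0 * g[p, q, i, i] - g[p, i, i, q]
            h_eff[a, b] = val
    g_act = g[np.ix_(active, active, active, active)]
    return IntegralSet(
        n_orbitals=n_act,
        n_electrons=space.n_active_electrons,
        core_energy=float(e_core),
        one_body=h_eff,
        two_body=g_act,
    )


def spin_orbital_index(spatial: int, spin: int, n_orbitals: int) -> int:
    """Blocked spin-orbital index: alpha block first, then beta block."""
    if spin not in (0, 1):
        raise ValueError("spin must be 0 (alpha) or 1 (beta)")
    if not (0 <= spatial < n_orbitals):
        raise ValueError(f"spatial orbital {spatial} out of range")
    return spatial + spin * n_orbitals


def build_fermionic_hamiltonian(ints: IntegralSet, space: ActiveSpace | None = None) -> FermionOperator:
    """Second-quantized active-space Hamiltonian as a ladder-operator sum.

    With ``space`` given, frozen-core folding is applied first; with
    ``space=None`` the full orbital set is used verbatim.  Spin orbitals use
    the blocked layout of :func:`spin_orbital_index`.
    """
    if space is not None:
        ints = freeze_core(ints, space)
    n = ints.n_orbitals
    op = FermionOperator()
    if ints.core_energy:
        op.add_term((), ints.core_energy)
    h, g = ints.one_body, ints.two_body
    for p in range(n):
        for q in range(n):
            if abs(h[p, q]) < 1e-14:
                continue
            for spin in (0, 1):
                ps = spin_orbital_index(p, spin, n)
                qs = spin_orbital_index(q, spin, n)
                op.add_term(((ps, True), (qs, False)), float(h[p, q]))
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s in range(n):
                    val = g[p, q, r, s]
                    if abs(val) < 1e-14:
                        continue
                    for sig in (0, 1):
                        for tau in (0, 1):
                            ps = spin_orbital_index(p, sig, n)
                            qs = spin_orbital_index(q, sig, n)
                            rs = spin_orbital_index(r, tau, n)
                            ss = spin_orbital_index(s, tau, n)
                            if ps == rs or qs == ss:
                                continue
                            op.add_term(
                                ((ps, True), (rs, True), (ss, False), (qs, False)),
                                0.5 * float(val),
                            )
    return op


def build_qubit_hamiltonian(ints: IntegralSet, space: ActiveSpace | None = None) -> QubitHamiltonian:
    """Active-space Hamiltonian mapped to qubits via Jordan-Wigner."""
    folded = freeze_core(ints, space) if space is not None else ints
    op = build_fermionic_hamiltonian(folded, None)
    return jordan_wigner(op, 2 * folded.n_orbitals)
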