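"""Molecular formulas, basis-counting rules, geometries and active-space bookkeeping.

Qubit-resource arithmetic for electronic-structure calculations: a minimal
basis assigns a fixed number of spatial orbitals per atom, every spatial
orbital contributes two spin orbitals, and a Jordan-Wigner style encoding
needs one qubit per spin orbital.  Active-space selection (core orbitals
frozen doubly occupied, external orbitals dropped) is what makes molecules
of realistic size fit on a simulator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ActiveSpaceError, InputError, UnknownElementError

__all__ = [
    "MolecularFormula",
    "BasisRules",
    "MolecularGeometry",
    "ActiveSpace",
    "STO3G",
    "count_spatial_orbitals",
    "qubit_requirement",
    "validate_active_space",
    "select_active_space",
    "read_xyz",
]

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

_KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Fe Cu Zn Br I".split()
)


@dataclass(frozen=True)
class MolecularFormula:
    """Element composition of a molecule, e.g. protocatechuic acid C7H6O4."""

    element_counts: dict[str, int]

    def __post_init__(self):
        if not self.element_counts:
            raise ValueError("formula must contain at least one element")
        for sym, n in self.element_counts.items():
            if n < 1:
                raise ValueError(f"count for element {sym!r} must be >= 1, got {n}")

    @classmethod
    def parse(cls, hill: str) -> "MolecularFormula":
        """Parse a Hill-notation formula string such as ``"C7H6O4"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _ELEMENT_RE.finditer(hill):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {hill!r} at position {pos}")
            sym, digits = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
            pos = m.end()
        if pos != len(hill) or not counts:
            raise ValueError(f"cannot parse formula {hill!r}")
        return cls(counts)

    def merge(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for sym, n in other.element_counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return MolecularFormula(counts)

    def __str__(self) -> str:
        return "".join(
            f"{sym}{n if n > 1 else ''}" for sym, n in sorted(self.element_counts.items())
        )


@dataclass(frozen=True)
class BasisRules:
    """Per-element spatial-orbital counts for a named basis set.

    The shipped default covers the minimal STO-3G rules for first-row
    organic chemistry: H contributes a single 1s orbital; C, N and O each
    contribute 1s, 2s, 2px, 2py, 2pz (five spatial orbitals).  Other
    elements must be supplied explicitly.
    """

    basis_name: str
    orbitals_per_element: dict[str, int]

    def __post_init__(self):
        for sym, n in self.orbitals_per_element.items():
            if n < 1:
                raise ValueError(f"orbital count for {sym!r} must be >= 1, got {n}")

    def with_elements(self, extra: dict[str, int]) -> "BasisRules":
        merged = dict(self.orbitals_per_element)
        merged.update(extra)
        return BasisRules(self.basis_name, merged)


#: Minimal-basis counting rules for the elements this package targets.
STO3G = BasisRules("STO-3G", {"H": 1, "C": 5, "N": 5, "O": 5})


@dataclass(frozen=True)
class MolecularGeometry:
    """Atomic coordinates in Angstrom with total charge and spin multiplicity."""

    atoms: tuple[tuple[str, float, float, float], ...]
    charge: int = 0
    spin_multiplicity: int = 1

    def __post_init__(self):
        if self.spin_multiplicity < 1:
            raise ValueError("spin multiplicity must be a positive integer")
        for sym, x, y, z in self.atoms:
            if sym not in _KNOWN_ELEMENTS:
                raise ValueError(f"unknown element symbol {sym!r}")
            for c in (x, y, z):
                if not (c == c and abs(c) != float("inf")):
                    raise ValueError(f"non-finite coordinate for atom {sym}")

    @property
    def formula(self) -> MolecularFormula:
        counts: dict[str, int] = {}
        for sym, *_ in self.atoms:
            counts[sym] = counts.get(sym, 0) + 1
        return MolecularFormula(counts)


@dataclass(frozen=True)
class ActiveSpace:
    """An (n_electrons, n_orbitals) active window over a larger orbital set.

    Core orbitals ``{0 .. n_core_orbitals-1}`` are frozen doubly occupied;
    ``active_orbital_indices`` lists the spatial orbitals treated explicitly.
    """

    n_active_electrons: int
    n_active_orbitals: int
    n_core_orbitals: int = 0
    active_orbital_indices: tuple[int, ...] = field(default=())

    def __post_init__(self):
        if self.n_active_electrons < 1 or self.n_active_orbitals < 1:
            raise ActiveSpaceError("active electron and orbital counts must be positive")
        if self.n_core_orbitals < 0:
            raise ActiveSpaceError("core orbital count must be non-negative")
        if self.n_active_electrons > 2 * self.n_active_orbitals:
            raise ActiveSpaceError(
                f"{self.n_active_electrons} electrons do not fit in "
                f"{self.n_active_orbitals} spatial orbitals"
            )
        if not self.active_orbital_indices:
            start = self.n_core_orbitals
            object.__setattr__(
                self,
                "active_orbital_indices",
                tuple(range(start, start + self.n_active_orbitals)),
            )
        idx = self.active_orbital_indices
        if len(idx) != self.n_active_orbitals:
            raise ActiveSpaceError(
                f"expected {self.n_active_orbitals} active indices, got {len(idx)}"
            )
        if len(set(idx)) != len(idx):
            raise ActiveSpaceError("active orbital indices must be distinct")
        core = set(range(self.n_core_orbitals))
        overlap = core.intersection(idx)
        if overlap:
            raise ActiveSpaceError(
                f"active orbitals {sorted(overlap)} overlap the frozen core"
            )

    @property
    def n_spin_orbitals(self) -> int:
        return 2 * self.n_active_orbitals

    @property
    def n_qubits(self) -> int:
        return qubit_requirement(self.n_active_orbitals)

    def __str__(self) -> str:
        return f"({self.n_active_electrons}e,{self.n_active_orbitals}o)"


def count_spatial_orbitals(formula: MolecularFormula, rules: BasisRules = STO3G) -> int:
    """Total spatial-orbital count of ``formula`` under per-element basis rules.

    For protocatechuic acid (C7H6O4) in STO-3G this is
    ``7*5 + 6*1 + 4*5 = 61``.
    """
    total = 0
    for sym, n in formula.element_counts.items():
        if sym not in rules.orbitals_per_element:
            raise UnknownElementError(
                f"element {sym!r} has no orbital count in basis {rules.basis_name!r}"
            )
        total += n * rules.orbitals_per_element[sym]
    return total


def qubit_requirement(n_spatial_orbitals: int) -> int:
    """Qubits needed to encode ``n_spatial_orbitals`` under one qubit per spin orbital."""
    if n_spatial_orbitals < 0:
        raise ValueError("orbital count must be non-negative")
    return 2 * n_spatial_orbitals


def validate_active_space(
    space: ActiveSpace, n_total_orbitals: int, n_total_electrons: int
) -> ActiveSpace:
    """Check electron accounting and index ranges of ``space`` against the full system.

    The frozen core holds exactly ``2 * n_core_orbitals`` electrons, so the
    total electron count must equal ``2*n_core + n_active_electrons``.
    """
    if n_total_orbitals < space.n_core_orbitals + space.n_active_orbitals:
        raise ActiveSpaceError(
            f"system has {n_total_orbitals} orbitals but the space needs "
            f"{space.n_core_orbitals} core + {space.n_active_orbitals} active"
        )
    expected = 2 * space.n_core_orbitals + space.n_active_electrons
    if n_total_electrons != expected:
        raise ActiveSpaceError(
            f"electron accounting mismatch: system has {n_total_electrons} electrons "
            f"but 2*{space.n_core_orbitals} core + {space.n_active_electrons} active "
            f"= {expected}"
        )
    for i in space.active_orbital_indices:
        if not (0 <= i < n_total_orbitals):
            raise ActiveSpaceError(
                f"active orbital index {i} out of range for {n_total_orbitals} orbitals"
            )
    return space


def select_active_space(
    n_total_electrons: int,
    n_active_electrons: int,
    n_active_orbitals: int,
) -> ActiveSpace:
    """Build the default Fermi-level-centred active space.

    Freezes the lowest ``(n_total_electrons - n_active_electrons)/2`` orbitals
    and takes the next ``n_active_orbitals`` orbitals in the energy order the
    integrals are given in, i.e. the highest occupied plus lowest virtual
    window around the Fermi level.
    """
    remainder = n_total_electrons - n_active_electrons
    if remainder < 0 or remainder % 2:
        raise ActiveSpaceError(
            f"cannot freeze {remainder} electrons into doubly occupied core orbitals"
        )
    return ActiveSpace(
        n_active_electrons=n_active_electrons,
        n_active_orbitals=n_active_orbitals,
        n_core_orbitals=remainder // 2,
    )


def read_xyz(stream) -> MolecularGeometry:
    """Read a standard XYZ file: count line, comment line, ``El x y z`` records."""
    lines = [ln for ln in stream.read().splitlines()]
    if len(lines) < 2:
        raise InputError("XYZ stream too short: need count line and comment line")
    try:
        n_atoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise InputError(f"bad XYZ atom-count line: {lines[0]!r}") from exc
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) < n_atoms:
        raise InputError(f"XYZ declares {n_atoms} atoms but holds {len(records)}")
    atoms = []
    for ln in records[:n_atoms]:
        parts = ln.split()
        if len(parts) < 4:
            raise InputError(f"bad XYZ atom record: {ln!r}")
        try:
            atoms.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise InputError(f"bad XYZ coordinates in record: {ln!r}") from exc
    return MolecularGeometry(atoms=tuple(atoms))
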