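"""The six benchmark ansatz circuits: hardware-efficient v1-v5 and UCCSD.

The five hardware-efficient (HE) circuits are shallow layered circuits over
``N`` qubits whose first ``N/2`` qubits play the role of the occupied
("HOMO-layer") spin orbitals and the second half the virtual ones:

* **v1** — Hadamards on the occupied half, a CNOT layer mixing occupied with
  virtual qubits, a CNOT layer mixing within each half (spin mixing), then
  one rotation per qubit (RX on the occupied half, RY on the virtual half).
  ``N`` parameters, ``5N/2`` gates.
* **v2** — Hadamards on *all* qubits, the occupied-virtual CNOT layer, one
  rotation per qubit.  ``N`` parameters, ``5N/2`` gates.
* **v3** — Hadamards on all qubits with enlarged rotation layers
  interleaved with CNOTs.  ``2(3N-2)`` parameters, ``15N/2`` gates.
* **v4** — v1 with the rotation kinds swapped (RY half then RX half).
* **v5** — Hadamards on all qubits, CNOT coupling restricted to pairs inside
  the occupied half, one RY per qubit.  ``N`` parameters, ``9N/4`` gates.

UCCSD prepares the Hartree-Fock determinant with X gates and applies a
single-Trotter-step exponential of the anti-Hermitian cluster operator
``T - T†`` over all spin-conserving single and double excitations, one
parameter per excitation, each exponentiated Pauli term realized with the
standard basis-change / CNOT-ladder / RZ construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ArityError, GateError, VQEBenchError
from .operators import FermionOperator, jordan_wigner_complex
from .simulator import Gate, Statevector, apply_circuit, init_state

__all__ = [
    "CircuitTemplate",
    "ParameterVector",
    "HE_VERSIONS",
    "build_hardware_efficient",
    "build_uccsd",
    "uccsd_excitations",
    "counts",
    "bind",
    "draw",
]

HE_VERSIONS = ("v1", "v2", "v3", "v4", "v5")


@dataclass(frozen=True)
class CircuitTemplate:
    """An ordered parameterized gate list defining the unitary U(theta)."""

    n_qubits: int
    gates: tuple[Gate, ...]
    n_parameters: int

    def __post_init__(self):
        slots = set()
        for g in self.gates:
            if any(q >= self.n_qubits for q in g.qubits):
                raise GateError(
                    f"gate {g.kind} on {g.qubits} exceeds {self.n_qubits} qubits"
                )
            if g.parameter_slot is not None:
                slots.add(g.parameter_slot)
        if slots != set(range(self.n_parameters)):
            raise ArityError(
                f"parameter slots {sorted(slots)} do not cover "
                f"0..{self.n_parameters - 1}"
            )

    @property
    def n_gates(self) -> int:
        return len(self.gates)


@dataclass(frozen=True)
class ParameterVector:
    """A concrete assignment of the trainable angles theta (radians)."""

    values: tuple[float, ...]

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("parameter values must be finite")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def zeros(cls, n: int) -> "ParameterVector":
        return cls((0.0,) * n)

    @classmethod
    def uniform_random(cls, n: int, seed: int,
                       low: float = -np.pi, high: float = np.pi) -> "ParameterVector":
        rng = np.random.default_rng(seed)
        return cls(tuple(rng.uniform(low, high, size=n)))


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise VQEBenchError(message)


def _pairs_within(qubits: Sequence[int]) -> list[tuple[int, int]]:
    return [(qubits[2 * i], qubits[2 * i + 1]) for i in range(len(qubits) // 2)]


def build_hardware_efficient(version: str, n_qubits: int) -> CircuitTemplate:
    """Construct one of the five HE circuits for an ``n_qubits`` register.

    All versions require ``n_qubits`` divisible by 4: the spin-mixing and
    HOMO-layer CNOT pairings act on non-overlapping adjacent pairs within a
    half, so each half must have even size (and the v5 gate count ``9N/4``
    must be integral).
    """
    if version not in HE_VERSIONS:
        raise VQEBenchError(
            f"unknown HE version {version!r}; valid: {', '.join(HE_VERSIONS)}"
        )
    n = n_qubits
    _require(n >= 4, f"HE circuits need at least 4 qubits, got {n}")
    _require(n % 4 == 0,
             f"HE circuit {version} needs n_qubits divisible by 4, got {n}")
    half = n // 2
    occupied = list(range(half))
    virtual = list(range(half, n))
    ov_cnots = [(i, i + half) for i in occupied]
    spin_cnots = _pairs_within(occupied) + _pairs_within(virtual)

    gates: list[Gate] = []
    slot = itertools.count()

    def rot(kind: str, q: int) -> Gate:
        return Gate(kind, (q,), parameter_slot=next(slot))

    if version in ("v1", "v4"):
        gates += [Gate("H", (q,)) for q in occupied]
        gates += [Gate("CNOT", pair) for pair in ov_cnots]
        gates += [Gate("CNOT", pair) for pair in spin_cnots]
        first, second = ("RX", "RY") if version == "v1" else ("RY", "RX")
        gates += [rot(first, q) for q in occupied]
        gates += [rot(second, q) for q in virtual]
    elif version == "v2":
        gates += [Gate("H", (q,)) for q in range(n)]
        gates += [Gate("CNOT", pair) for pair in ov_cnots]
        gates += [rot("RX", q) for q in occupied]
        gates += [rot("RY", q) for q in virtual]
    elif version == "v3":
        gates += [Gate("H", (q,)) for q in range(n)]
        for q in range(n):
            gates += [rot("RX", q), rot("RY", q)]
        gates += [Gate("CNOT", pair) for pair in ov_cnots]
        for q in range(n):
            gates += [rot("RX", q), rot("RY", q)]
        # four spin-mixing CNOTs at the edges of each half
        gates += [
            Gate("CNOT", (0, 1)),
            Gate("CNOT", (half - 2, half - 1)),
            Gate("CNOT", (half, half + 1)),
            Gate("CNOT", (n - 2, n - 1)),
        ]
        for q in range(1, n - 1):
            gates += [rot("RX", q), rot("RY", q)]
    else:  # v5
        gates += [Gate("H", (q,)) for q in range(n)]
        gates += [Gate("CNOT", pair) for pair in _pairs_within(occupied)]
        gates += [rot("RY", q) for q in range(n)]

    n_params = next(slot)
    return CircuitTemplate(n, tuple(gates), n_params)


def uccsd_excitations(n_electrons: int, n_spin_orbitals: int):
    """Spin-conserving single and double excitations from the HF determinant.

    Occupied spin orbitals are those of the blocked-layout HF state; singles
    preserve the spin of the moved electron, doubles preserve total Sz.
    Singles come first, each list sorted lexicographically.
    """
    from .refci import hartree_fock_determinant

    hf = hartree_fock_determinant(n_electrons, n_spin_orbitals)
    occ = hf.occupied
    virt = tuple(p for p in range(n_spin_orbitals) if p not in occ)
    if not virt:
        raise VQEBenchError("no virtual spin orbitals: no excitations exist")
    n_orb = n_spin_orbitals // 2
    spin = lambda p: p // n_orb

    singles = [(i, a) for i in occ for a in virt if spin(i) == spin(a)]
    singles.sort()
    doubles = []
    for i, j in itertools.combinations(occ, 2):
        for a, b in itertools.combinations(virt, 2):
            if sorted((spin(i), spin(j))) == sorted((spin(a), spin(b))):
                doubles.append((i, j, a, b))
    doubles.sort()
    return singles, doubles


def _exponentiated_pauli_gates(pauli_terms: dict, slot: int) -> list[Gate]:
    """Gates realizing prod_k exp(i theta h_k P_k) for commuting terms P_k.

    Each term: map X to the Z basis with H, Y with RX(pi/2); accumulate
    parity along a CNOT ladder; rotate RZ(-2 h_k theta) on the last qubit;
    undo.
    """
    gates: list[Gate] = []
    for ps, coeff in sorted(pauli_terms.items(), key=lambda kv: str(kv[0])):
        if abs(coeff.real) > 1e-12:
            raise GateError("excitation generator must be anti-Hermitian")
        h_k = coeff.imag
        qubits = [q for q, _ in ps.factors]
        labels = {q: lab for q, lab in ps.factors}
        pre: list[Gate] = []
        post: list[Gate] = []
        for q in qubits:
            if labels[q] == "X":
                pre.append(Gate("H", (q,)))
                post.append(Gate("H", (q,)))
            elif labels[q] == "Y":
                pre.append(Gate("RX", (q,), angle=np.pi / 2))
                post.append(Gate("RX", (q,), angle=-np.pi / 2))
        ladder = [Gate("CNOT", (qubits[i], qubits[i + 1]))
                  for i in range(len(qubits) - 1)]
        gates += pre + ladder
        gates.append(Gate("RZ", (qubits[-1],), parameter_slot=slot, scale=-2.0 * h_k))
        gates += list(reversed(ladder)) + list(reversed(post))
    return gates


def build_uccsd(n_electrons: int, n_spin_orbitals: int) -> CircuitTemplate:
    """Single-Trotter-step UCCSD circuit with HF preparation.

    At theta = 0 every exponential is the identity, so the circuit prepares
    exactly the Hartree-Fock basis state.
    """
    if not (0 < n_electrons <= n_spin_orbitals):
        raise VQEBenchError(
            f"need 0 < n_electrons <= n_spin_orbitals, got "
            f"({n_electrons}, {n_spin_orbitals})"
        )
    from .refci import hartree_fock_determinant

    singles, doubles = uccsd_excitations(n_electrons, n_spin_orbitals)
    hf = hartree_fock_determinant(n_electrons, n_spin_orbitals)
    gates: list[Gate] = [Gate("X", (q,)) for q in hf.occupied]

    slot = 0
    for i, a in singles:
        t = FermionOperator({((a, True), (i, False)): 1.0})
        generator = t - t.hermitian_conjugate()
        gates += _exponentiated_pauli_gates(jordan_wigner_complex(generator), slot)
        slot += 1
    for i, j, a, b in doubles:
        t = FermionOperator({((a, True), (b, True), (j, False), (i, False)): 1.0})
        generator = t - t.hermitian_conjugate()
        gates += _exponentiated_pauli_gates(jordan_wigner_complex(generator), slot)
        slot += 1
    return CircuitTemplate(n_spin_orbitals, tuple(gates), slot)


def counts(template: CircuitTemplate) -> tuple[int, int]:
    """(n_parameters, n_gates) of a template."""
    return template.n_parameters, template.n_gates


def bind(template: CircuitTemplate, theta: ParameterVector,
         initial: Statevector) -> Statevector:
    """Apply U(theta) to ``initial``: the prepared trial state |psi(theta)>."""
    if len(theta) != template.n_parameters:
        raise ArityError(
            f"template has {template.n_parameters} parameters, "
            f"got {len(theta)} values"
        )
    if initial.n_qubits != template.n_qubits:
        raise ArityError(
            f"template acts on {template.n_qubits} qubits, "
            f"state has {initial.n_qubits}"
        )
    return apply_circuit(initial, template.gates, theta.values)


def hartree_fock_state(n_electrons: int, n_spin_orbitals: int) -> Statevector:
    """The HF determinant as a computational basis state."""
    from .refci import hartree_fock_determinant

    hf = hartree_fock_determinant(n_electrons, n_spin_orbitals)
    return init_state(n_spin_orbitals, list(hf.occupation))


def draw(template: CircuitTemplate) -> str:
    """A plain-text one-gate-per-line rendering of the template."""
    lines = [f"{template.n_qubits} qubits, {template.n_parameters} parameters"]
    for g in template.gates:
        if g.parameter_slot is not None:
            angle = f"theta[{g.parameter_slot}]"
            if g.scale != 1.0:
                angle = f"{g.scale:+.6g}*{angle}"
            if g.angle:
                angle += f"{g.angle:+.6g}"
        elif g.kind in ("RX", "RY", "RZ"):
            angle = f"{g.angle:.6g}"
        else:
            angle = ""
        q = ",".join(str(q) for q in g.qubits)
        lines.append(f"  {g.kind}({q})" + (f" {angle}" if angle else ""))
    return "\n".join(lines)
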