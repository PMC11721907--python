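# vqebench

Benchmarking variational-quantum-eigensolver (VQE) ansatzes against exact
classical references for active-space molecular ground states.

## What this is for

The VQE estimates a molecular ground-state energy by minimizing

    E(θ) = ⟨ψ(θ)| H |ψ(θ)⟩ ≥ E₀,    |ψ(θ)⟩ = U(θ)|ψ₀⟩

over the parameters θ of a quantum circuit U(θ). How well it works depends
almost entirely on two modelling choices: the **ansatz** (the circuit
family) and the **active space** (which molecular orbitals are treated
explicitly, with the rest frozen). This package gives computational
chemists and quantum-algorithm researchers a self-contained, exactly
simulable testbed for those choices:

* qubit-resource arithmetic from molecular formulas (STO-3G counting rules:
  protocatechuic acid C7H6O4 → 61 spatial orbitals → 122 qubits; a (4e,4o)
  active space → 8 qubits),
* FCIDUMP integral input, synthetic integral generation, frozen-core
  folding and the Jordan–Wigner qubit Hamiltonian,
* an exact statevector simulator (gates, Pauli-sum expectations, full and
  sector-restricted diagonalization),
* six ansatz constructions — five hardware-efficient circuits v1–v5 with
  verifiable gate/parameter-count formulas, plus single-Trotter UCCSD,
* a gradient-descent VQE loop with analytically exact gradients and
  seventh-decimal (1e-7 Ha) convergence accounting,
* determinant-CI references: full CI (FCI, the exact answer in the space)
  and CISD, computed by Slater–Condon rules independently of the qubit
  representation.

The two independent routes to the ground energy — determinant CI and the
Jordan–Wigner qubit Hamiltonian — agree to 1e-9 Ha on every fixture, which
is the package's core correctness check. See `docs/methods.md` for models,
conventions and numerical choices.

## Worked example

Resource arithmetic for the motivating molecule:

```
$ vqebench count C7H6O4 --active-space 4,4 --active-space 8,8
formula:           C7H6O4
spatial orbitals:  61
spin orbitals:     122
qubits (full):     122
qubits (4e,4o):   8
qubits (8e,8o):   16
```

61 = 7·5 + 6·1 + 4·5 spatial orbitals under the STO-3G per-atom rules; one
qubit per spin orbital puts the full molecule at 122 qubits, while the
(4e,4o) active window needs only 8.

Classical references and a VQE run on the packaged H2 fixture
(STO-3G, 0.7414 Å bond length):

```
$ vqebench reference --source h2
FCI:                 -1.1372655544 Ha
CISD:                -1.1372655544 Ha
JW ground (any sector): -1.1372655544 Ha

$ vqebench vqe --source h2 --ansatz uccsd --init zeros
ansatz:     uccsd (3 parameters, 150 gates)
energy:     -1.1372654764 Ha
steps:      17
converged:  True
```

FCI and CISD coincide because singles and doubles exhaust all excitations
of two electrons, and −1.1373 Ha is the textbook H2/STO-3G total energy.
Starting from the Hartree–Fock state (θ = 0), UCCSD-VQE converges in 17
steps to within 8e-8 Ha of FCI — UCCSD is exact for two-electron systems,
so the only gap is the optimizer's stopping rule.

The full benchmark matrix (six ansatzes × one active space, with FCI/CISD
reference rows) on a synthetic (4e,4o) system:

```
$ vqebench bench --source random:4o4e:1 --active-space 4,4 --seed 1 --out bench_out
```

writes `energies.csv` and `steps.csv` (ansatz rows × active-space columns),
per-cell `trajectories/*.csv` (step, energy — the convergence curves), and
`run_meta.json` (full config echo for provenance). Hardware-efficient
circuits do not conserve particle number, so their energies may drop below
the sector-FCI reference while still obeying the variational bound of the
full spectrum; UCCSD is number-conserving and lands closest to FCI, which
is the qualitative ranking this benchmark is designed to expose.

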