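# Methods

This note documents the models, conventions and numerical choices behind
`vqebench`. It is the place to look when a result needs interpreting or a
default needs questioning.

## Problem setting

The package studies how ansatz design and active-space size affect the
variational quantum eigensolver (VQE) when estimating molecular ground-state
energies. The motivating system is protocatechuic acid (C7H6O4, a
plant-derived phenolic antioxidant): in the minimal STO-3G basis it needs 61
spatial orbitals, i.e. 122 spin orbitals and 122 qubits under a one-qubit-
per-spin-orbital encoding — far beyond exact statevector simulation. The
workflow therefore freezes core orbitals and restricts the calculation to an
active window around the Fermi level: (4e,4o), (6e,6o) and (8e,8o) spaces
mapping to 8, 12 and 16 qubits.

## Electronic Hamiltonian

Inputs are restricted Hartree–Fock molecular-orbital integrals, read from
FCIDUMP text or generated synthetically. Two-electron integrals are stored
in chemists' notation `(ij|kl)` with their eightfold permutational symmetry
enforced on read (symmetric completion) and checked on construction
(tolerance 1e-10).

Frozen-core folding replaces the full Hamiltonian by an active-space one:

    E_core' = E_nuc + 2 Σ_i h_ii + Σ_ij [2(ii|jj) − (ij|ij)]
    h'_pq   = h_pq + Σ_i [2(pq|ii) − (pi|iq)]

with `i, j` over core and `p, q` over active spatial orbitals. The folded
constant is carried through every representation, so all reported energies
are total energies (nuclear repulsion included).

Spin orbitals use a **blocked layout**: for `n` active spatial orbitals,
spin orbitals (and qubits) `0..n-1` are the alpha set in ascending orbital
order, `n..2n-1` the beta partners. "Ascending" means the order the
integrals are given in (FCIDUMP order); no re-diagonalization is attempted.
The blocked choice makes the "first half of the register" language of the
hardware-efficient circuits meaningful and is asserted by convention tests;
it differs from the interleaved (alternating alpha/beta) convention some
simulators use, which is the classic source of silent cross-framework bugs.

The Jordan–Wigner transformation maps ladder operators to Pauli strings
with Z-parity chains. Products are tracked internally in the symplectic
(X-mask, Z-mask) representation where multiplication is XOR plus a sign;
coefficients below 1e-12 are dropped after collection, and an imaginary
residue above 1e-8 on any collected coefficient raises a Hermiticity error.

## Simulator

Dense statevector simulation with qubit 0 as the **most significant** bit of
the amplitude index. All operations are pure (new state out, inputs
untouched) and norm-preserving; expectation values are exact (no sampling
noise — the benchmark isolates ansatz expressiveness and optimizer
behaviour from shot noise). Global phases are not normalized away; tests
compare up to phase where relevant.

Exact diagonalization builds the Hamiltonian matrix from the mask-based
Pauli action. Registers up to 12 qubits use a dense solver; 13–16 qubits
fall back to sparse Lanczos (a 16-qubit dense matrix would need ~69 GB, so
a dense-only path to 16 qubits is not realistic). Particle-number/Sz
sectors can be diagonalized directly through `sector_matrix`, which builds
only the relevant block by bit arithmetic and never materializes the 2^n
matrix — this is how determinant-CI energies are cross-checked against the
qubit representation up to 16 qubits.

## Ansatz circuits

Five hardware-efficient circuits (v1–v5) plus UCCSD. The published count
formulas — v1/v2/v4: (N, 5N/2), v3: (2(3N−2), 15N/2), v5: (N, 9N/4) — are
enforced as structural acceptance constraints on the layouts. Where the
circuit diagrams leave wiring open, the transcription fixes it as:
occupied→virtual CNOTs pair qubit `i` with `i+N/2`; spin-mixing CNOTs pair
non-overlapping adjacent qubits within each half; v3's four extra CNOTs sit
at the edges of each half and its third rotation layer covers qubits
`1..N−2` (giving exactly 2N−4 extra parameters); v5's rotation layer is RY
on every qubit. Because the within-half pairings need each half to be of
even size, all versions require `N` divisible by 4 — which covers every
register size the benchmark uses (8, 12, 16, and 4 for tests). v4 is v1
with the RX/RY rotation kinds exchanged site by site.

Hardware-efficient circuits start from |0…0⟩ (their Hadamard layer creates
the occupation pattern); they do **not** conserve particle number, so their
variational floor is the ground energy of the full Fock space, not of the
N-electron sector. This is visible in benchmark output: an HE energy may
drop below the sector FCI reference while still respecting the variational
bound of the full spectrum.

UCCSD applies a single Trotter step of `exp(T − T†)` to the Hartree–Fock
determinant (prepared by X gates), with one parameter per spin-conserving
single and double excitation, singles first, each block ordered
lexicographically. Each excitation generator is Jordan–Wigner-mapped; its
Pauli terms mutually commute, so the per-excitation exponential factorizes
exactly into the standard basis-change / CNOT-ladder / RZ constructions.
The RZ angles are the shared excitation parameter scaled by twice the term
coefficient, so one parameter drives several rotations. At θ = 0 the
circuit prepares exactly the HF state; for two-electron systems UCCSD spans
the full Sz-conserving CI space and is exact.

Whether a deeper (multi-Trotter) UCCSD is ever warranted was left open;
a single step is implemented and is already exact where the benchmark
checks exactness.

## Optimization

Plain gradient descent is the default (`step_size` 0.1, `max_steps` 2000),
with Adam as a second built-in; the outer-loop method is deliberately
pluggable because nothing in the benchmark protocol pins it down. Parameter
initialization is uniform on (−π, π) from an explicit seed, with zeros
available (the natural HF start for UCCSD). All randomness flows from the
seed; identical configurations produce bit-identical trajectories.

Gradients are exact, by two interchangeable routes:

* **Parameter shift** — per rotation-gate occurrence `g` with scale `s_g`,
  the contribution is `s_g · [C(+π/2) − C(−π/2)]/2` with the shift applied
  to that occurrence only. For one unit-scale gate per parameter this is the
  textbook two-point rule; summing occurrences makes it exact for the
  scaled multi-gate parameters of UCCSD too.
* **Adjoint differentiation** — one forward sweep, one application of H and
  one backward sweep undoing gates, accumulating `s · Im⟨k|P|b⟩` per
  occurrence. Numerically identical (tested to 1e-10) at a fraction of the
  cost, and therefore the optimizer's default.

Convergence follows the seventh-decimal rule: stop at the first step whose
energy differs from its predecessor by less than 1e-7 Ha; that step index
(1-based, counting energy evaluations) is the reported
`steps_to_convergence`. A parameter-change criterion was considered and
rejected — the protocol being reproduced is defined on energies. Note the
rule measures *stalling*, not optimality: a flat landscape (v1 is the
standard example) can "converge" in 2 steps far above the ground state, and
this behaviour is reported as-is. Runs exhausting `max_steps` report
`converged = False` rather than raising; NaN/inf energies raise an
optimization error carrying the partial trajectory.

## Classical references

FCI and CISD are computed by explicit determinant CI with Slater–Condon
matrix elements over the same blocked spin-orbital layout, entirely
independent of the qubit path — the two routes meeting at 1e-9 Ha is the
package's core correctness argument, exercised on every fixture. Sz
conservation is on by default (closed-shell targets); CISD excites from the
closed-shell reference within the active space, consistent with quoting
CISD per active-orbital count. The dense CI solver caps the determinant
dimension at 8192, which covers the (8e,8o) space (C(8,4)² = 4900).

## Synthetic data

`random_integral_set(n, n_elec, seed)` emulates a well-behaved closed-shell
molecule near its HF minimum: sorted diagonal orbital energies in
(−2, 1.5) Ha with symmetric off-diagonal noise (σ = 0.05), dominant
positive Coulomb diagonals `(ii|jj)` in (0.3, 0.7) Ha over weak fully
symmetrized two-body noise (σ = 0.02), and a positive constant standing in
for nuclear repulsion. It reproduces the *structure* real integrals have
(symmetries, HF-like ordering, sector spectra) but not their values — so
passing tests demonstrate representation-equivalence, variational bounds and
optimizer behaviour, not agreement with any particular molecule's energies.
Absolute energies of the motivating molecule are not reproducible here in
any case: its geometry and exact active-orbital choice are not available,
which is why the acceptance battery is property-based (cross-representation
agreement, UCCSD-vs-FCI exactness, variational ordering) rather than a
table of absolute energies.

The packaged `h2` fixture is the exception with real physics: tabulated
H2/STO-3G integrals at the 0.7414 Å equilibrium geometry, where the
computed FCI energy (−1.1372656 Ha) lands on the textbook value.

## Benchmark sizes and runtime

The shipped benchmark matrix runs six ansatzes on a synthetic (4e,4o)
space — 8 qubits, 361 Pauli terms — with FCI/CISD references; on one CPU
core this completes in a few minutes, dominated by the UCCSD cells (~2400
gates per circuit evaluation). The 12- and 16-qubit spaces are supported by
the same code paths (sector CI up to (8e,8o), sparse diagonalization to 16
qubits) and are simply larger runs of the same matrix.

## Known limitations

* No shot noise, hardware noise models, or device backends; conclusions
  about optimizer step counts transfer only qualitatively to hardware.
* No point-group symmetry, complex integrals, or relativistic terms.
* Active orbitals default to the Fermi-level-centred window in integral
  order; a chemistry-driven orbital choice (e.g. pi-system selection) must
  be supplied explicitly via `active_orbital_indices`.
* Gradient descent with a fixed step is deliberately simple; it can stall
  on plateaus (v1) and its step counts depend on the landscape, which is
  part of what the benchmark measures.
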