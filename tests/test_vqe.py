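"""Cost function, gradients and the optimization loop."""

import numpy as np
import pytest

from vqebench.ansatz import (
    CircuitTemplate,
    ParameterVector,
    build_hardware_efficient,
    build_uccsd,
)
from vqebench.errors import VQEBenchError
from vqebench.hamiltonian import build_qubit_hamiltonian, random_integral_set
from vqebench.operators import PauliString, QubitHamiltonian
from vqebench.refci import ci_ground_energy, hf_energy
from vqebench.simulator import Gate, exact_spectrum, init_state
from vqebench.vqe import (
    OptimizerConfig,
    cost,
    gradient,
    gradient_adjoint,
    minimize,
)


def ry_z_problem():
    """One RY on |0>: cost(theta) = cos(theta), exactly solvable."""
    template = CircuitTemplate(1, (Gate("RY", (0,), parameter_slot=0),), 1)
    h = QubitHamiltonian(1, {PauliString(((0, "Z"),)): 1.0})
    return template, h


class TestCost:
    def test_constant_hamiltonian(self):
        t = build_hardware_efficient("v1", 4)
        h = QubitHamiltonian(4, {PauliString(): 3.0})
        theta = ParameterVector.uniform_random(t.n_parameters, seed=0)
        assert cost(theta, t, h, init_state(4)) == pytest.approx(3.0)

    def test_uccsd_at_zero_equals_hf_energy(self, h2_integrals):
        """The untouched HF determinant reproduces the Slater-rule HF energy."""
        h = build_qubit_hamiltonian(h2_integrals)
        t = build_uccsd(2, 4)
        e = cost(ParameterVector.zeros(t.n_parameters), t, h, init_state(4))
        assert e == pytest.approx(hf_energy(h2_integrals), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_variational_lower_bound(self, seed, h2_integrals):
        h = build_qubit_hamiltonian(h2_integrals)
        ground = exact_spectrum(h, k=1)[0]
        t = build_hardware_efficient("v3", 4)
        theta = ParameterVector.uniform_random(t.n_parameters, seed=seed)
        assert cost(theta, t, h, init_state(4)) >= ground - 1e-9


class TestGradient:
    def test_closed_form_ry(self):
        t, h = ry_z_problem()
        s = init_state(1)
        # cost = cos(theta): gradient -sin(theta)
        assert gradient(ParameterVector((0.0,)), t, h, s)[0] == pytest.approx(0.0)
        assert gradient(ParameterVector((np.pi / 2,)), t, h, s)[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("builder,n_args", [
        (build_hardware_efficient, ("v3", 4)),
        (build_uccsd, (2, 4)),
    ])
    def test_matches_finite_differences(self, builder, n_args):
        t = builder(*n_args)
        ints = random_integral_set(2, 2, seed=21)
        h = build_qubit_hamiltonian(ints)
        theta = ParameterVector.uniform_random(t.n_parameters, seed=3)
        s = init_state(4)
        grad = gradient(theta, t, h, s)
        eps = 1e-5
        base = np.asarray(theta.values)
        for k in range(t.n_parameters):
            plus = cost(ParameterVector(tuple(base + eps * np.eye(len(base))[k])), t, h, s)
            minus = cost(ParameterVector(tuple(base - eps * np.eye(len(base))[k])), t, h, s)
            assert grad[k] == pytest.approx((plus - minus) / (2 * eps), abs=1e-4)

    @pytest.mark.parametrize("builder,n_args", [
        (build_hardware_efficient, ("v1", 4)),
        (build_hardware_efficient, ("v3", 4)),
        (build_uccsd, (2, 4)),
    ])
    def test_adjoint_equals_parameter_shift(self, builder, n_args):
        t = builder(*n_args)
        ints = random_integral_set(2, 2, seed=22)
        h = build_qubit_hamiltonian(ints)
        theta = ParameterVector.uniform_random(t.n_parameters, seed=4)
        s = init_state(4)
        np.testing.assert_allclose(
            gradient_adjoint(theta, t, h, s), gradient(theta, t, h, s), atol=1e-10
        )


class TestMinimize:
    def test_zero_parameter_template_converges_at_step_one(self):
        t = CircuitTemplate(2, (Gate("H", (0,)),), 0)
        h = QubitHamiltonian(2, {PauliString(((1, "Z"),)): 1.0})
        res = minimize(t, h, init_state(2), OptimizerConfig())
        assert res.steps_to_convergence == 1
        assert res.converged
        assert res.energy == pytest.approx(1.0)

    def test_uccsd_reaches_fci_on_h2(self, h2_integrals):
        h = build_qubit_hamiltonian(h2_integrals)
        t = build_uccsd(2, 4)
        res = minimize(t, h, init_state(4),
                       OptimizerConfig(init_scheme="zeros"))
        assert res.converged
        assert res.energy == pytest.approx(ci_ground_energy(h2_integrals), abs=1e-6)

    def test_deterministic_for_fixed_seed(self, h2_integrals):
        h = build_qubit_hamiltonian(h2_integrals)
        t = build_hardware_efficient("v2", 4)
        cfg = OptimizerConfig(seed=7, max_steps=50)
        r1 = minimize(t, h, init_state(4), cfg)
        r2 = minimize(t, h, init_state(4), cfg)
        assert r1.trajectory.energies == r2.trajectory.energies
        assert r1.trajectory.parameters_final == r2.trajectory.parameters_final

    def test_descent_improves_energy(self, h2_integrals):
        h = build_qubit_hamiltonian(h2_integrals)
        t = build_hardware_efficient("v3", 4)
        res = minimize(t, h, init_state(4), OptimizerConfig(seed=3, max_steps=200))
        assert res.energy <= res.trajectory.energies[0]

    def test_bound_holds_at_every_step(self, h2_integrals):
        h = build_qubit_hamiltonian(h2_integrals)
        ground = exact_spectrum(h, k=1)[0]
        t = build_hardware_efficient("v5", 4)
        res = minimize(t, h, init_state(4), OptimizerConfig(seed=5, max_steps=300))
        assert all(e >= ground - 1e-9 for e in res.trajectory.energies)

    def test_convergence_rule_matches_trajectory(self, h2_integrals):
        """steps_to_convergence is the first step within 1e-7 Ha of its predecessor."""
        h = build_qubit_hamiltonian(h2_integrals)
        t = build_uccsd(2, 4)
        cfg = OptimizerConfig(init_scheme="zeros")
        res = minimize(t, h, init_state(4), cfg)
        e = res.trajectory.energies
        diffs = [abs(e[i] - e[i - 1]) for i in range(1, len(e))]
        first = next(i + 2 for i, d in enumerate(diffs) if d < cfg.convergence_tol)
        assert res.steps_to_convergence == first
        assert all(d >= cfg.convergence_tol for d in diffs[:first - 2])

    def test_max_steps_exhaustion_reports_not_converged(self, h2_integrals):
        h = build_qubit_hamiltonian(h2_integrals)
        t = build_hardware_efficient("v3", 4)
        res = minimize(t, h, init_state(4), OptimizerConfig(seed=1, max_steps=5))
        assert not res.converged
        assert res.steps_to_convergence == 5
        assert len(res.trajectory.energies) == 5

    def test_adam_also_minimizes(self, h2_integrals):
        h = build_qubit_hamiltonian(h2_integrals)
        t = build_hardware_efficient("v2", 4)
        res = minimize(t, h, init_state(4),
                       OptimizerConfig(method="adam", step_size=0.05,
                                       seed=2, max_steps=300))
        assert res.energy < res.trajectory.energies[0]

    def test_invalid_config_rejected(self):
        with pytest.raises(VQEBenchError):
            OptimizerConfig(method="newton")
        with pytest.raises(VQEBenchError):
            OptimizerConfig(step_size=-1.0)
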