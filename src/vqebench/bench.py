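"""The ansatz x active-space benchmark matrix and its CSV reports.

One benchmark run sweeps a list of ansatz labels over a list of active
spaces on one integral source, computing for every (ansatz, space) cell the
converged VQE energy and the number of steps to seventh-decimal convergence,
alongside the FCI and CISD reference energies per space.  Reports are
written as RFC-4180 CSV files shaped like the result tables such a study
prints: an energy table (ansatz rows + CISD + FCI rows, one column per
space), a steps table, and per-cell optimization trajectories.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .ansatz import HE_VERSIONS, build_hardware_efficient, build_uccsd
from .errors import ConfigError, InputError
from .fixtures import fixture_integrals, fixture_names
from .hamiltonian import (
    IntegralSet,
    build_qubit_hamiltonian,
    random_integral_set,
    read_fcidump,
)
from .molsys import ActiveSpace, select_active_space
from .refci import ci_ground_energy
from .simulator import init_state
from .vqe import OptimizerConfig, VQEResult, minimize

__all__ = [
    "ANSATZ_LABELS",
    "BenchmarkConfig",
    "BenchmarkRow",
    "BenchmarkResult",
    "resolve_integral_source",
    "run_benchmark",
    "write_reports",
    "read_reports",
]

logger = logging.getLogger("vqebench")

ANSATZ_LABELS = HE_VERSIONS + ("uccsd",)

_RANDOM_SOURCE = re.compile(r"random:(\d+)o(\d+)e(?::(\d+))?$")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Everything one benchmark run depends on."""

    integral_source: str
    active_spaces: tuple[ActiveSpace, ...]
    ansatzes: tuple[str, ...]
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    output_dir: str = "bench_out"

    def __post_init__(self):
        if not self.active_spaces:
            raise ConfigError("at least one active space is required")
        if not self.ansatzes:
            raise ConfigError("at least one ansatz label is required")
        for label in self.ansatzes:
            if label not in ANSATZ_LABELS:
                raise ConfigError(
                    f"unknown ansatz {label!r}; valid: {', '.join(ANSATZ_LABELS)}"
                )


@dataclass
class BenchmarkRow:
    ansatz: str
    space: ActiveSpace
    energy: float | None
    steps: int | None
    converged: bool
    error: str | None = None


@dataclass
class BenchmarkResult:
    rows: list[BenchmarkRow]
    references: dict[str, tuple[float, float]]  # space label -> (fci, cisd)
    trajectories: dict[tuple[str, str], list[float]]
    config: BenchmarkConfig


def resolve_integral_source(source: str, seed: int = 0) -> IntegralSet:
    """Resolve an integral source string.

    Accepts a packaged fixture name (``h2``), a generator spec
    ``random:<n_orbitals>o<n_electrons>e[:<seed>]``, or an FCIDUMP path.
    """
    if source in fixture_names():
        return fixture_integrals(source)
    m = _RANDOM_SOURCE.match(source)
    if m:
        n_orb, n_elec = int(m.group(1)), int(m.group(2))
        src_seed = int(m.group(3)) if m.group(3) is not None else seed
        return random_integral_set(n_orb, n_elec, src_seed)
    path = Path(source)
    if path.exists():
        with open(path) as fh:
            return read_fcidump(fh)
    raise InputError(
        f"cannot resolve integral source {source!r}: not a fixture "
        f"({', '.join(fixture_names())}), not a random:<N>o<M>e spec, "
        "and no such file exists"
    )


def _run_cell(label: str, h, space: ActiveSpace, cfg: OptimizerConfig) -> VQEResult:
    n_qubits = space.n_qubits
    if label == "uccsd":
        template = build_uccsd(space.n_active_electrons, n_qubits)
    else:
        template = build_hardware_efficient(label, n_qubits)
    # UCCSD prepares HF with its leading X gates; HE circuits create
    # occupation themselves, so both start from |0...0>.
    return minimize(template, h, init_state(n_qubits), cfg)


def run_benchmark(cfg: BenchmarkConfig) -> BenchmarkResult:
    """Run every (ansatz, active-space) cell plus the classical references.

    Per-cell failures are recorded in the row's ``error`` field rather than
    aborting the sweep.  Deterministic for a fixed config (the optimizer
    seed covers all randomness).
    """
    ints = resolve_integral_source(cfg.integral_source, seed=cfg.optimizer.seed)
    rows: list[BenchmarkRow] = []
    references: dict[str, tuple[float, float]] = {}
    trajectories: dict[tuple[str, str], list[float]] = {}

    for space in cfg.active_spaces:
        label_space = str(space)
        h = build_qubit_hamiltonian(ints, space)
        fci = ci_ground_energy(ints, space, level="FCI")
        cisd = ci_ground_energy(ints, space, level="CISD")
        references[label_space] = (fci, cisd)
        logger.info("space %s: FCI=%.10f CISD=%.10f (%d qubits, %d Pauli terms)",
                    label_space, fci, cisd, h.n_qubits, h.n_terms)
        for label in cfg.ansatzes:
            try:
                result = _run_cell(label, h, space, cfg.optimizer)
            except Exception as exc:  # noqa: BLE001 - per-row isolation
                logger.warning("cell (%s, %s) failed: %s", label, label_space, exc)
                rows.append(BenchmarkRow(label, space, None, None, False, str(exc)))
                continue
            logger.info("cell (%s, %s): E=%.10f steps=%d converged=%s",
                        label, label_space, result.energy,
                        result.steps_to_convergence, result.converged)
            rows.append(BenchmarkRow(label, space, result.energy,
                                     result.steps_to_convergence, result.converged))
            trajectories[(label, label_space)] = list(result.trajectory.energies)
    return BenchmarkResult(rows, references, trajectories, cfg)


def _space_labels(result: BenchmarkResult) -> list[str]:
    seen = []
    for space in result.config.active_spaces:
        if str(space) not in seen:
            seen.append(str(space))
    return seen


def write_reports(result: BenchmarkResult, output_dir: str | Path) -> list[Path]:
    """Write energies.csv, steps.csv, trajectories/*.csv and run_meta.json."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    spaces = _space_labels(result)
    ansatzes = list(result.config.ansatzes)

    cells_energy = {(r.ansatz, str(r.space)): r.energy for r in result.rows}
    cells_steps = {(r.ansatz, str(r.space)): r.steps for r in result.rows}

    def fmt(v):
        return "" if v is None else repr(v)

    energies = out / "energies.csv"
    with open(energies, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ansatz"] + spaces)
        for label in ansatzes:
            writer.writerow([label] + [fmt(cells_energy.get((label, s))) for s in spaces])
        writer.writerow(["CISD"] + [fmt(result.references[s][1]) for s in spaces])
        writer.writerow(["FCI"] + [fmt(result.references[s][0]) for s in spaces])
    written.append(energies)

    steps = out / "steps.csv"
    with open(steps, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ansatz"] + spaces)
        for label in ansatzes:
            writer.writerow([label] + [fmt(cells_steps.get((label, s))) for s in spaces])
    written.append(steps)

    if result.trajectories:
        traj_dir = out / "trajectories"
        traj_dir.mkdir(exist_ok=True)
        for (label, space), energies_list in result.trajectories.items():
            safe_space = space.strip("()").replace(",", "_")
            path = traj_dir / f"{label}_{safe_space}.csv"
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["step", "energy_hartree"])
                for step, e in enumerate(energies_list, start=1):
                    writer.writerow([step, repr(e)])
            written.append(path)

    meta = out / "run_meta.json"
    cfg = result.config
    with open(meta, "w") as fh:
        json.dump(
            {
                "package_version": __version__,
                "integral_source": cfg.integral_source,
                "active_spaces": [
                    {
                        "n_active_electrons": s.n_active_electrons,
                        "n_active_orbitals": s.n_active_orbitals,
                        "n_core_orbitals": s.n_core_orbitals,
                        "active_orbital_indices": list(s.active_orbital_indices),
                    }
                    for s in cfg.active_spaces
                ],
                "ansatzes": list(cfg.ansatzes),
                "optimizer": {
                    "method": cfg.optimizer.method,
                    "step_size": cfg.optimizer.step_size,
                    "max_steps": cfg.optimizer.max_steps,
                    "convergence_tol": cfg.optimizer.convergence_tol,
                    "seed": cfg.optimizer.seed,
                    "init_scheme": cfg.optimizer.init_scheme,
                    "gradient_mode": cfg.optimizer.gradient_mode,
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    written.append(meta)
    return written


def read_reports(output_dir: str | Path) -> tuple[dict, dict, dict]:
    """Parse energies.csv / steps.csv / references back into dictionaries.

    Returns (energies, steps, references) keyed by (row label, space label);
    the inverse of :func:`write_reports` up to float round-trip (which is
    exact, since values are written with ``repr``).
    """
    out = Path(output_dir)
    energies: dict = {}
    steps: dict = {}
    references: dict = {}
    with open(out / "energies.csv", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        spaces = header[1:]
        for row in reader:
            label = row[0]
            for space, value in zip(spaces, row[1:]):
                if value == "":
                    continue
                target = references if label in ("FCI", "CISD") else energies
                target[(label, space)] = float(value)
    with open(out / "steps.csv", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        spaces = header[1:]
        for row in reader:
            for space, value in zip(spaces, row[1:]):
                if value != "":
                    steps[(row[0], space)] = int(value)
    return energies, steps, references
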