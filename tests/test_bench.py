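"""Benchmark sweep, CSV report shapes and the command-line interface."""

import csv

import pytest
from click.testing import CliRunner

from vqebench.bench import (
    ANSATZ_LABELS,
    BenchmarkConfig,
    read_reports,
    resolve_integral_source,
    run_benchmark,
    write_reports,
)
from vqebench.cli import main
from vqebench.errors import ConfigError, InputError
from vqebench.molsys import ActiveSpace
from vqebench.vqe import OptimizerConfig


@pytest.fixture(scope="module")
def small_result():
    """One (2e,2o) space, two ansatzes, short optimizer budget."""
    cfg = BenchmarkConfig(
        integral_source="random:2o2e:5",
        active_spaces=(ActiveSpace(2, 2),),
        ansatzes=("v1", "uccsd"),
        optimizer=OptimizerConfig(seed=3, max_steps=60),
    )
    return run_benchmark(cfg)


class TestIntegralSource:
    def test_fixture_name_resolves(self):
        ints = resolve_integral_source("h2")
        assert (ints.n_orbitals, ints.n_electrons) == (2, 2)

    def test_random_spec_resolves_deterministically(self):
        a = resolve_integral_source("random:3o4e:9")
        b = resolve_integral_source("random:3o4e:9")
        assert a == b

    def test_fcidump_path_resolves(self, tmp_path, h2_integrals):
        from vqebench.hamiltonian import write_fcidump

        p = tmp_path / "h2.fcidump"
        with open(p, "w") as fh:
            write_fcidump(h2_integrals, fh)
        assert resolve_integral_source(str(p)) == h2_integrals

    def test_unresolvable_source_is_input_error(self):
        with pytest.raises(InputError):
            resolve_integral_source("no_such_thing")


class TestRunBenchmark:
    def test_row_cardinality(self, small_result):
        assert len(small_result.rows) == 2  # 2 ansatzes x 1 space
        assert set(small_result.references) == {"(2e,2o)"}

    def test_energies_respect_fci_floor(self, small_result):
        # HE rows may dip below sector-FCI (they explore all particle
        # sectors) but never below the CISD>=FCI ordering of the references
        fci, cisd = small_result.references["(2e,2o)"]
        assert fci <= cisd + 1e-12
        uccsd_row = next(r for r in small_result.rows if r.ansatz == "uccsd")
        assert uccsd_row.energy >= fci - 1e-9

    def test_invalid_ansatz_label_rejected(self):
        with pytest.raises(ConfigError, match="uccsd"):
            BenchmarkConfig(
                integral_source="h2",
                active_spaces=(ActiveSpace(2, 2),),
                ansatzes=("v1", "nope"),
            )

    def test_empty_lists_rejected(self):
        with pytest.raises(ConfigError):
            BenchmarkConfig("h2", (), ("v1",))
        with pytest.raises(ConfigError):
            BenchmarkConfig("h2", (ActiveSpace(2, 2),), ())


class TestReports:
    def test_energies_csv_shape(self, small_result, tmp_path):
        write_reports(small_result, tmp_path)
        with open(tmp_path / "energies.csv", newline="") as fh:
            rows = list(csv.reader(fh))
        assert rows[0] == ["ansatz", "(2e,2o)"]
        assert [r[0] for r in rows[1:]] == ["v1", "uccsd", "CISD", "FCI"]

    def test_steps_csv_shape(self, small_result, tmp_path):
        write_reports(small_result, tmp_path)
        with open(tmp_path / "steps.csv", newline="") as fh:
            rows = list(csv.reader(fh))
        assert rows[0] == ["ansatz", "(2e,2o)"]
        assert [r[0] for r in rows[1:]] == ["v1", "uccsd"]
        for r in rows[1:]:
            assert int(r[1]) <= 60

    def test_trajectories_written_per_cell(self, small_result, tmp_path):
        write_reports(small_result, tmp_path)
        names = {p.name for p in (tmp_path / "trajectories").iterdir()}
        assert names == {"v1_2e_2o.csv", "uccsd_2e_2o.csv"}

    def test_round_trip(self, small_result, tmp_path):
        write_reports(small_result, tmp_path)
        energies, steps, references = read_reports(tmp_path)
        for row in small_result.rows:
            key = (row.ansatz, str(row.space))
            assert energies[key] == row.energy
            assert steps[key] == row.steps
        fci, cisd = small_result.references["(2e,2o)"]
        assert references[("FCI", "(2e,2o)")] == fci
        assert references[("CISD", "(2e,2o)")] == cisd

    def test_rerun_is_byte_identical(self, small_result, tmp_path):
        cfg = small_result.config
        again = run_benchmark(cfg)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_reports(small_result, d1)
        write_reports(again, d2)
        for name in ("energies.csv", "steps.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


class TestCLI:
    def test_count_command(self):
        runner = CliRunner()
        res = runner.invoke(main, ["count", "C7H6O4",
                                   "--active-space", "4,4",
                                   "--active-space", "8,8"])
        assert res.exit_code == 0
        assert "spatial orbitals:  61" in res.output
        assert "spin orbitals:     122" in res.output
        assert "qubits (4e,4o):   8" in res.output
        assert "qubits (8e,8o):   16" in res.output

    def test_reference_command_on_h2(self):
        runner = CliRunner()
        res = runner.invoke(main, ["reference", "--source", "h2"])
        assert res.exit_code == 0
        assert "-1.1372655" in res.output

    def test_hamiltonian_dump(self):
        runner = CliRunner()
        res = runner.invoke(main, ["hamiltonian", "--fixture", "h2"])
        assert res.exit_code == 0
        assert "4 qubits" in res.output and "Z0" in res.output

    def test_vqe_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "traj.csv"
        res = runner.invoke(main, [
            "vqe", "--source", "h2", "--ansatz", "uccsd", "--init", "zeros",
            "--trajectory-out", str(out),
        ])
        assert res.exit_code == 0
        assert "converged:  True" in res.output
        assert out.exists()

    def test_bench_command_writes_reports(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(main, [
            "bench", "--source", "random:2o2e:5", "--active-space", "2,2",
            "--ansatz", "v2", "--max-steps", "40", "--out", str(tmp_path / "o"),
        ])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "o" / "energies.csv").exists()
        assert (tmp_path / "o" / "run_meta.json").exists()

    def test_bench_config_file(self, tmp_path):
        cfg = tmp_path / "bench.yaml"
        cfg.write_text(
            "source: random:2o2e:5\n"
            "ansatzes: [v5]\n"
            "active_spaces: ['2,2']\n"
        )
        runner = CliRunner()
        res = runner.invoke(main, ["bench", "--config", str(cfg),
                                   "--max-steps", "40",
                                   "--out", str(tmp_path / "o")])
        assert res.exit_code == 0, res.output
        with open(tmp_path / "o" / "energies.csv", newline="") as fh:
            rows = list(csv.reader(fh))
        assert [r[0] for r in rows] == ["ansatz", "v5", "CISD", "FCI"]

    def test_bench_without_space_is_config_error(self):
        runner = CliRunner()
        res = runner.invoke(main, ["bench", "--source", "h2"])
        assert res.exit_code == 2

    def test_bench_bad_source_is_input_error(self):
        runner = CliRunner()
        res = runner.invoke(main, ["bench", "--source", "missing.fcidump",
                                   "--active-space", "2,2"])
        assert res.exit_code == 3

    def test_unknown_element_fails_cleanly(self):
        runner = CliRunner()
        res = runner.invoke(main, ["count", "UUU9"])
        assert res.exit_code != 0
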