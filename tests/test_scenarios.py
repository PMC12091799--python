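"""Patient presets, table regeneration, synthetic observations, fitting, CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

from ffrt.cli import main as cli_main
from ffrt.ffsolver import SimulationGrid
from ffrt.kernels import FractionalSpec
from ffrt.scenarios import (
    TABLE_MUS,
    TABLE_TIMES,
    all_presets,
    least_squares_fit,
    load_config,
    patient_preset,
    reproduce_tables,
    round_half_away,
    save_config,
    synthesize_observations,
)

SHARED_RATES = dict(alpha1=9.7041e-4, alpha2=0.3396, beta1=0.0433, beta2=0.2385,
                    K1=1.0, K2=1.0, epsilon=0.0008)


class TestPresets:
    @pytest.mark.parametrize(
        "patient,arm,gamma,x0",
        [
            (1, "high", 0.75, 0.284),
            (1, "low", 0.35, 0.284),
            (2, "high", 0.65, 0.174),
            (2, "low", 0.35, 0.174),
            (3, "high", 0.85, 0.306),
            (3, "low", 0.35, 0.306),
        ],
    )
    def test_published_values(self, patient, arm, gamma, x0):
        scen = patient_preset(patient, arm)
        assert scen.params.gamma == gamma
        assert scen.init.x1 == x0 and scen.init.x2 == x0
        for name, value in SHARED_RATES.items():
            assert getattr(scen.params, name) == value

    def test_six_scenarios(self):
        labels = {s.label for s in all_presets()}
        assert len(labels) == 6

    def test_unknown_selector_rejected(self):
        with pytest.raises(ValueError):
            patient_preset(4, "high")
        with pytest.raises(ValueError):
            patient_preset(1, "medium")


class TestConfigRoundTrip:
    def test_bit_exact(self, tmp_path):
        scen = patient_preset(2, "high")
        path = tmp_path / "scenario.cfg"
        values = {
            **{k: getattr(scen.params, k) for k in SHARED_RATES},
            "gamma": scen.params.gamma,
            "x1_0": scen.init.x1,
            "x2_0": scen.init.x2,
            "mu": 0.85,
            "dt": 0.05,
        }
        save_config(path, values)
        loaded = load_config(path)
        assert loaded == values  # repr round-trip is exact for floats

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("nonsense = 1\n")
        with pytest.raises(ValueError):
            load_config(path)


class TestRounding:
    def test_half_away_from_zero(self):
        assert round_half_away(0.00005) == 0.0001
        assert round_half_away(0.12345) == 0.1235
        assert round_half_away(1.0) == 1.0


@pytest.fixture(scope="module")
def table_artifact():
    # coarse step, no confirmation run: structural checks only
    return reproduce_tables(1, nu=1.0, dt=0.2, check_convergence=False)


class TestReproduceTables:
    def test_grid_shape_and_labels(self, table_artifact):
        art = table_artifact
        for df in (art.normal, art.cancer, art.diff_normal, art.diff_cancer):
            assert list(df.index) == list(TABLE_TIMES)
            assert list(df.columns) == list(TABLE_MUS)

    def test_discrepancy_report_emitted(self, table_artifact, tmp_path):
        art = table_artifact
        assert (art.diff_cancer.values >= 0).all()
        assert art.diff_cancer.values.max() > 0  # published values not reproduced
        text = art.summary()
        assert "discrepancy" in text
        art.write(tmp_path)
        assert (tmp_path / "patient1_nu1_report.txt").exists()
        assert (tmp_path / "patient1_nu1_cancer_diff.csv").exists()

    def test_cancer_cells_monotone_down_each_column(self, table_artifact):
        c = table_artifact.cancer.values
        assert (np.diff(c, axis=0) <= 0).all()

    def test_cancer_cells_monotone_in_memory_order(self, table_artifact):
        c = table_artifact.cancer.values
        assert (np.diff(c, axis=1) <= 0).all()

    def test_published_extinction_cells_confirmed_by_printed_fixture(self):
        from ffrt.scenarios import PRINTED_TABLES

        assert PRINTED_TABLES[1]["cancer"][2][3] == 0.0  # patient 1, t=150, mu=1
        assert PRINTED_TABLES[2]["cancer"][2][3] == 0.0  # patient 2, t=150, mu=1
        assert PRINTED_TABLES[3]["cancer"][3][3] == 0.0  # patient 3, t=200, mu=1


class TestSyntheticObservations:
    def test_zero_noise_reproduces_trajectory(self, patient1, classical_spec):
        grid = SimulationGrid.for_horizon(20.0, 0.5)
        obs1, obs2 = synthesize_observations(patient1, classical_spec, grid, 0.0, seed=5)
        from ffrt.ffsolver import integrate_ffm

        traj = integrate_ffm(patient1.params, classical_spec, grid, patient1.init)
        np.testing.assert_array_equal(obs1.values, traj.x1)
        np.testing.assert_array_equal(obs2.values, traj.x2)

    def test_seed_determinism(self, patient1, classical_spec):
        grid = SimulationGrid.for_horizon(20.0, 0.5)
        a = synthesize_observations(patient1, classical_spec, grid, 0.01, seed=9)
        b = synthesize_observations(patient1, classical_spec, grid, 0.01, seed=9)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_residual_standard_deviation_matches_request(self, patient1, classical_spec):
        grid = SimulationGrid.for_horizon(99.5, 0.5)  # 200 points
        sds = []
        for seed in range(5):
            obs1, obs2 = synthesize_observations(
                patient1, classical_spec, grid, 0.005, seed=seed
            )
            from ffrt.ffsolver import integrate_ffm

            traj = integrate_ffm(patient1.params, classical_spec, grid, patient1.init)
            resid = np.concatenate([obs1.values - traj.x1, obs2.values - traj.x2])
            sds.append(resid.std())
        assert 0.004 < np.mean(sds) < 0.006


class TestLeastSquaresFit:
    def test_zero_noise_recovers_dose_rate(self, patient1, classical_spec):
        grid = SimulationGrid.for_horizon(99.5, 0.5)
        obs = synthesize_observations(patient1, classical_spec, grid, 0.0, seed=1)
        res = least_squares_fit(
            obs, patient1, ["gamma"], {"gamma": (0.1, 2.0)}, classical_spec, grid, seed=2
        )
        assert res.values["gamma"] == pytest.approx(0.75, abs=1e-4)
        assert res.converged

    def test_two_parameter_zero_noise_self_consistency(self, patient1, classical_spec):
        grid = SimulationGrid.for_horizon(49.5, 0.5)
        obs = synthesize_observations(patient1, classical_spec, grid, 0.0, seed=1)
        res = least_squares_fit(
            obs, patient1, ["alpha2", "gamma"],
            {"alpha2": (0.05, 1.0), "gamma": (0.1, 2.0)},
            classical_spec, grid, seed=2,
        )
        assert res.rss <= 1e-10

    def test_requires_free_parameter_and_bounds(self, patient1, classical_spec):
        grid = SimulationGrid.for_horizon(10.0, 0.5)
        obs = synthesize_observations(patient1, classical_spec, grid, 0.0, seed=1)
        with pytest.raises(ValueError):
            least_squares_fit(obs, patient1, [], {}, classical_spec, grid)
        with pytest.raises(ValueError):
            least_squares_fit(obs, patient1, ["gamma"], {}, classical_spec, grid)


class TestCLI:
    def test_analyze_reports_thresholds_and_verdicts(self):
        result = CliRunner().invoke(cli_main, ["analyze", "--patient", "1", "--arm", "high"])
        assert result.exit_code == 0
        assert "R0" in result.output and "0.343551" in result.output
        assert "gamma*eps < alpha1 : True" in result.output
        assert "Matignon E0" in result.output

    def test_simulate_writes_deterministic_csv(self, tmp_path):
        args = ["simulate", "--patient", "1", "--arm", "high", "--mu", "1",
                "--nu", "1", "--dt", "0.1", "--t-end", "20"]
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        r1 = CliRunner().invoke(cli_main, args + ["-o", str(a)])
        r2 = CliRunner().invoke(cli_main, args + ["-o", str(b)])
        assert r1.exit_code == 0 and r2.exit_code == 0
        assert a.read_bytes() == b.read_bytes()

    def test_tables_emits_report(self):
        result = CliRunner().invoke(
            cli_main,
            ["tables", "--patient", "3", "--nu", "1", "--dt", "0.4",
             "--no-convergence-check"],
        )
        assert result.exit_code == 0
        assert "discrepancy" in result.output

    def test_lyapunov_trace_export(self, tmp_path):
        out = tmp_path / "trace.csv"
        result = CliRunner().invoke(
            cli_main,
            ["lyapunov", "--patient", "1", "--arm", "high", "--dt", "0.1",
             "--t-end", "30", "-o", str(out)],
        )
        assert result.exit_code == 0
        header = out.read_text().splitlines()[1]
        assert header == "t,L,upsilon1,upsilon2,dLdt,dLdt_chain,d2Ldt2"

    def test_fit_smoke(self):
        result = CliRunner().invoke(
            cli_main,
            ["fit", "--patient", "1", "--arm", "high", "--dt", "1.0",
             "--t-end", "50", "--noise-sd", "0", "--seed", "3"],
        )
        assert result.exit_code == 0
        assert "gamma: fitted" in result.output

    def test_usage_error_exits_nonzero(self):
        result = CliRunner().invoke(cli_main, ["simulate", "--patient", "9", "-o", "x.csv"])
        assert result.exit_code != 0
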