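import numpy as np
import pandas as pd
import pytest

from fragiso.chem import natural_per_atom_ratio
from fragiso.errors import ConfigError, ValidationError
from fragiso.ion_stats import add_ion_counts, series_from_frame, window_ratio
from fragiso.pipeline import process_run
from fragiso.scan_io import RunConfig
from fragiso.simulate import (
    DegradationScenario,
    SimulationConfig,
    TrueState,
    parse_position_key,
    rayleigh_shift,
    simulate_bracketed_sequence,
    simulate_degradation,
    simulate_scan_table,
    simulate_standard_series,
)


class TestConfig:
    def test_invalid_split_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(fragment_split=1.5)

    def test_negative_drift_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(drift_rel_sd=-0.1)

    def test_from_dict_parses_position_keys(self):
        config = SimulationConfig.from_dict(
            {
                "seed": 5,
                "true_deltas": {"F99.N": 27.0},
                "response": {"F99.C": {"slope": 0.8, "intercept": 1.0}},
            }
        )
        assert config.true_deltas[("F99", "N")] == 27.0
        assert config.response[("F99", "C")] == (0.8, 1.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="bogus"):
            SimulationConfig.from_dict({"bogus": 1})

    def test_bad_position_key_rejected(self):
        with pytest.raises(ConfigError):
            parse_position_key("F99N")


class TestScanTable:
    def test_deterministic_for_fixed_seed(self):
        config = SimulationConfig(seed=3, duration_min=1.0)
        frame_a, _ = simulate_scan_table(config)
        frame_b, _ = simulate_scan_table(config)
        pd.testing.assert_frame_equal(frame_a, frame_b)

    def test_different_seeds_differ(self):
        a, _ = simulate_scan_table(SimulationConfig(seed=1, duration_min=1.0))
        b, _ = simulate_scan_table(SimulationConfig(seed=2, duration_min=1.0))
        assert not a["intensity"].equals(b["intensity"])

    def test_ion_counts_recovered_exactly(self):
        # inverting the ion-count estimate must reproduce the drawn integers
        config = SimulationConfig(seed=4, duration_min=1.0)
        frame, _ = simulate_scan_table(config)
        counted = add_ion_counts(frame)
        n_io = counted["n_io"].to_numpy()
        assert np.allclose(n_io, np.round(n_io), atol=1e-9)

    def test_law_of_large_numbers_ratio(self):
        config = SimulationConfig(
            seed=5, agc_target=1e9, duration_min=2.0, drift_rel_sd=0.0
        )
        frame, _ = simulate_scan_table(config)
        counted = add_ion_counts(frame)
        window = (0.0, 2.0)
        result = window_ratio(
            series_from_frame(counted, "F99-13C", window),
            series_from_frame(counted, "F99", window),
        )
        expected = 4 * natural_per_atom_ratio("C")
        assert result.ratio == pytest.approx(expected, rel=1e-3)

    def test_true_delta_moves_expected_ratio(self):
        config = SimulationConfig(
            seed=6,
            agc_target=1e9,
            duration_min=2.0,
            drift_rel_sd=0.0,
            true_deltas={("F92", "N"): 200.0},
        )
        frame, _ = simulate_scan_table(config)
        counted = add_ion_counts(frame)
        result = window_ratio(
            series_from_frame(counted, "F92-15N", (0.0, 2.0)),
            series_from_frame(counted, "F92", (0.0, 2.0)),
        )
        expected = natural_per_atom_ratio("N") * 1.2
        assert result.ratio == pytest.approx(expected, rel=1e-3)

    def test_truth_sidecar_round_trip(self, tmp_path):
        config = SimulationConfig(
            seed=8, duration_min=1.0, true_deltas={("F99", "N"): 27.0}
        )
        _, truth = simulate_scan_table(config)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        loaded = TrueState.from_json(path)
        assert loaded.true_deltas == truth.true_deltas
        assert loaded.seed == truth.seed


class TestBracketedSequence:
    def test_block_layout(self, null_sequence):
        frame, _ = null_sequence
        assert frame["time_min"].min() == pytest.approx(0.0)
        assert frame["time_min"].max() < 9 * 18.0

    def test_layout_constraint(self):
        with pytest.raises(ValidationError):
            simulate_bracketed_sequence(SimulationConfig(), n_reference=4, n_sample=4)

    def test_null_sequence_recovers_zero(self, null_sequence, run_config):
        frame, _ = null_sequence
        result = process_run(frame, run_config)
        for dv in result.delta_values:
            assert abs(dv.delta) < dv.ci95

    def test_shift_recovered_within_ci(self, shifted_sequence, run_config):
        frame, truth = shifted_sequence
        result = process_run(frame, run_config)
        by_position = result.by_position()
        for position, expected in truth.true_deltas.items():
            dv = by_position[position]
            assert dv.delta == pytest.approx(expected, abs=dv.ci95)


class TestPrecisionScaling:
    def test_sd_shrinks_with_sqrt_duration(self):
        # doubling the usable duration should shrink ratio scatter by sqrt(2)
        def ratio_sd(duration, seed0):
            values = []
            for seed in range(seed0, seed0 + 100):
                config = SimulationConfig(
                    seed=seed,
                    agc_target=2e5,
                    duration_min=duration,
                    scan_period_s=2.0,
                    drift_rel_sd=0.0,
                )
                frame, _ = simulate_scan_table(config)
                counted = add_ion_counts(frame)
                result = window_ratio(
                    series_from_frame(counted, "F99-15N", (0.0, duration)),
                    series_from_frame(counted, "F99", (0.0, duration)),
                )
                values.append(result.ratio)
            return np.std(values, ddof=1)

        shrinkage = ratio_sd(2.0, 0) / ratio_sd(4.0, 500)
        assert shrinkage == pytest.approx(np.sqrt(2.0), rel=0.15)


class TestStandardSeries:
    def test_mass_balance_f92_nitrogen(self):
        standards, _ = simulate_standard_series(
            [("F92", "N")], spike_targets=[100.0], ea_sd=0.0
        )
        assert standards[0].delta_bulk_shift == pytest.approx(100.0 / 3.0)
        assert standards[0].delta_calc("F92", "N") == pytest.approx(100.0)

    def test_mass_balance_f99_carbon(self):
        standards, _ = simulate_standard_series(
            [("F99", "C")], spike_targets=[200.0], ea_sd=0.0
        )
        assert standards[0].delta_bulk_shift == pytest.approx(80.0)

    def test_zero_ea_sd_gives_zero_spread(self):
        standards, records = simulate_standard_series(
            [("F92", "N")], spike_targets=[50.0], ea_sd=0.0
        )
        assert standards[0].sd == 0.0
        assert records[0].sd == 0.0

    def test_naming_and_counts(self):
        standards, records = simulate_standard_series(
            [("F92", "N"), ("F99", "C")], spike_targets=[50.0, 100.0, 200.0]
        )
        assert [s.standard_id for s in standards] == [
            "A1", "A2", "A3", "B1", "B2", "B3",
        ]
        assert len(records) == 6

    def test_invalid_position_rejected(self):
        with pytest.raises(ValidationError):
            simulate_standard_series([("F92", "O")], spike_targets=[50.0])

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValidationError):
            simulate_standard_series([("F92", "N")], spike_targets=[-10.0])


class TestDegradation:
    def test_rayleigh_closed_form(self):
        assert rayleigh_shift(-10.0, 0.5) == pytest.approx(6.931, abs=1e-3)

    def test_rayleigh_invalid_fraction(self):
        with pytest.raises(ValidationError):
            rayleigh_shift(-10.0, 0.0)

    def test_scenario_from_rayleigh(self):
        scenario = DegradationScenario.from_rayleigh(
            timepoints=[0.0, 2.0],
            remaining_fractions=[1.0, 0.5],
            epsilons={("F99", "N"): -10.0},
            initial_deltas={("F99", "N"): 2.0},
        )
        assert scenario.trajectories[("F99", "N")][0] == pytest.approx(2.0)
        assert scenario.trajectories[("F99", "N")][1] == pytest.approx(8.931, abs=1e-3)

    def test_trajectory_length_validated(self):
        with pytest.raises(ValidationError):
            DegradationScenario((0.0, 1.0), {("F99", "N"): (1.0,)})

    def test_one_sequence_per_timepoint(self):
        scenario = DegradationScenario(
            (0.0, 2.0), {("F99", "N"): (2.0, 27.0)}
        )
        config = SimulationConfig(seed=9, scan_period_s=24.0)
        results = simulate_degradation(scenario, config)
        assert len(results) == 2
        t0, frame0, truth0 = results[0]
        assert truth0.true_deltas[("F99", "N")] == 2.0
        assert results[1][2].true_deltas[("F99", "N")] == 27.0
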