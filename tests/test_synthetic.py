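"""Synthetic-data generator: population, threshold law, trial protocols."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import painlimits as pl
from painlimits.errors import InvalidArgumentError, SimulationLimitError
from painlimits.synthetic import staircase_peaks, read_trial, write_trial


class TestSamplePopulation:
    @pytest.mark.parametrize("n,frac,expected_males", [
        (40, 0.6, 24),
        (41, 0.0, 0),
        (20, 0.5, 10),
        (1, 1.0, 1),
    ])
    def test_male_count_follows_rounding_rule(self, n, frac, expected_males):
        roster = pl.sample_population(n, frac, seed=1)
        assert len(roster) == n
        assert sum(s.gender_code for s in roster) == expected_males

    def test_same_seed_gives_identical_roster(self):
        a = pl.sample_population(20, 0.5, seed=3)
        b = pl.sample_population(20, 0.5, seed=3)
        assert a == b

    def test_different_seed_changes_roster(self):
        a = pl.sample_population(20, 0.5, seed=3)
        b = pl.sample_population(20, 0.5, seed=4)
        assert a != b

    @pytest.mark.parametrize("n,frac", [(0, 0.5), (-1, 0.5), (10, -0.1), (10, 1.5)])
    def test_invalid_arguments_rejected(self, n, frac):
        with pytest.raises(InvalidArgumentError):
            pl.sample_population(n, frac, seed=0)


class TestDrawThreshold:
    def test_median_draw_is_exp_beta0(self, forehead_spec):
        assert pl.threshold_from_uniform(forehead_spec, 0, 0.5) == \
            pytest.approx(math.exp(4.22))

    def test_upper_quartile_closed_form(self, forehead_spec):
        # exp(4.22 + 0.46*ln 3) = 112.77
        assert pl.threshold_from_uniform(forehead_spec, 0, 0.75) == \
            pytest.approx(112.77, abs=0.01)

    def test_empirical_median_recovers_location(self):
        spec = pl.ThresholdSpec(12, "pinching", "blunt", 3.0, 0.5, 0.3)
        rng = np.random.default_rng(5)
        draws = [pl.draw_threshold(spec, 1, rng) for _ in range(100_000)]
        assert np.median(draws) == pytest.approx(math.exp(3.5), abs=0.3)

    def test_distributional_recovery_ks(self, forehead_spec, rng):
        draws = np.array([pl.draw_threshold(forehead_spec, 0, rng)
                          for _ in range(10_000)])
        stat, _ = stats.kstest(
            draws,
            lambda y: pl.expanded_cdf(y, 0.0, 4.22, 0.0, 0.46),
        )
        assert stat < 0.02

    def test_invalid_spec_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pl.ThresholdSpec(1, "pinching", "semi-sharp", 4.0, 0.0, -0.1)
        with pytest.raises(InvalidArgumentError):
            pl.ThresholdSpec(1, "pinching", "semi-sharp", 4.0, -0.2, 0.4)
        with pytest.raises(InvalidArgumentError):
            pl.ThresholdSpec(1, "squeezing", "semi-sharp", 4.0, 0.0, 0.4)


class TestAlgometerTrial:
    def _config(self, **kw):
        defaults = dict(contact_stiffness=50_000.0, noise_sd=0.0,
                        offset_sd=0.0, reaction_delay=0.0)
        defaults.update(kw)
        return pl.ProtocolConfig(**defaults)

    def test_event_one_second_after_contact(self, rng):
        # 50 N at 50 N/s ramp -> 1.0 s after contact
        trial = pl.simulate_algometer_trial(50.0, self._config(), rng)
        t_event = trial.time[trial.event_index] - 1.0
        assert t_event == pytest.approx(1.0, abs=0.011)
        assert trial.true_peak >= 50.0
        assert trial.sampling_rate == 100.0

    def test_constant_offset_shifts_baseline_only(self, rng):
        cfg = self._config()
        trial = pl.simulate_algometer_trial(50.0, cfg, rng)
        shifted = trial.force + 2.0
        baseline = shifted[:100, 0]
        assert baseline.mean() == pytest.approx(2.0)
        # offset elimination recovers the same measured force
        sig = pl.ForceSignal(trial.time, shifted, 100.0,
                             event_index=trial.event_index)
        clean = pl.eliminate_offset(sig, 0.9)
        assert pl.max_contact_force(clean, "algometer") == \
            pytest.approx(trial.true_peak, abs=0.02)

    def test_unreachable_threshold_raises(self, rng):
        with pytest.raises(SimulationLimitError):
            pl.simulate_algometer_trial(1e9, self._config(), rng)

    def test_force_at_event_tracks_threshold_under_noise(self):
        cfg = self._config(noise_sd=0.5, offset_sd=1.0)
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            trial = pl.simulate_algometer_trial(50.0, cfg, rng)
            sig = pl.cfc_filter(trial.to_signal(), "CFC1")
            sig = pl.eliminate_offset(sig, 0.9)
            errors.append(pl.max_contact_force(sig, "algometer") - 50.0)
        assert max(abs(e) for e in errors) < 2.0


class TestPendulumStaircase:
    def test_spec_arithmetic_example(self, rng):
        # sqrt(16.5 * 1.19e6) = 4431 N per m/s; pain at the second trial
        cfg = pl.ProtocolConfig(contact_stiffness=1.19e6, noise_sd=0.0,
                                offset_sd=0.0, velocity_start=0.005,
                                pendulum_masses=(16.5,))
        (series,) = pl.simulate_pendulum_staircase(140.0, cfg, rng)
        assert [t.pain for t in series] == [False, True]
        assert series[0].true_peak == pytest.approx(22.2, abs=0.1)
        assert series[1].true_peak == pytest.approx(243.7, abs=0.1)
        assert series[0].sampling_rate == 10_000.0

    def test_first_trial_pain_is_left_censored_case(self, rng):
        cfg = pl.ProtocolConfig(contact_stiffness=1.19e6, noise_sd=0.0,
                                pendulum_masses=(16.5,))
        (series,) = pl.simulate_pendulum_staircase(10.0, cfg, rng)
        assert len(series) == 1 and series[0].pain

    def test_no_pain_at_vmax_is_right_censored_case(self, rng):
        cfg = pl.ProtocolConfig(contact_stiffness=1000.0, noise_sd=0.0,
                                pendulum_masses=(16.5,))
        (series,) = pl.simulate_pendulum_staircase(1e6, cfg, rng)
        assert not any(t.pain for t in series)
        assert series[-1].v_p == pytest.approx(1.25)

    def test_velocities_increase_in_fixed_steps(self, rng):
        cfg = pl.ProtocolConfig(contact_stiffness=3e4, noise_sd=0.0)
        for series in pl.simulate_pendulum_staircase(200.0, cfg, rng):
            v = [t.v_p for t in series]
            assert np.allclose(np.diff(v), cfg.velocity_step)

    def test_one_series_per_mass(self, rng):
        cfg = pl.ProtocolConfig(contact_stiffness=3e4, noise_sd=0.0)
        staircases = pl.simulate_pendulum_staircase(150.0, cfg, rng)
        assert len(staircases) == 2
        assert staircases[0][0].m_p == 16.5
        assert staircases[1][0].m_p == 6.5

    @given(threshold=st.floats(min_value=5.0, max_value=2000.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_noiseless_staircase_brackets_threshold(self, threshold):
        cfg = pl.ProtocolConfig(contact_stiffness=3e4, noise_sd=0.0,
                                pendulum_masses=(16.5,))
        rng = np.random.default_rng(0)
        (series,) = staircase_peaks(threshold, cfg, rng, head=False)
        peaks = [p for p, _ in series]
        flags = [f for _, f in series]
        if flags[-1]:
            if len(peaks) == 1:
                assert threshold <= peaks[0]  # left-censored
            else:
                assert peaks[-2] < threshold <= peaks[-1]
        else:
            assert threshold > peaks[-1]  # right-censored


class TestPressureFrameSimulation:
    def test_uniform_profile_mean_pressure(self, rng):
        geo = pl.default_film_geometry()
        trial = pl.TrialSeries(
            time=np.array([0.0, 0.01]),
            force=np.full((2, 1), 100.0),
            sampling_rate=100.0, load_type="pinching",
        )
        frames = pl.simulate_pressure_frames(trial, geo, rng,
                                             profile_sigma_mm=None,
                                             quantize=False)
        unmasked = frames[0].grid[frames[0].coverage_mask]
        # 100 N over the 1.96 cm^2 face
        assert np.all(frames[0].grid[~frames[0].coverage_mask] == 0)
        assert unmasked.mean() == pytest.approx(100.0 / 1.96, rel=1e-6)

    def test_quantized_levels_are_8bit(self, rng):
        geo = pl.default_film_geometry()
        trial = pl.TrialSeries(
            time=np.array([0.0, 0.01]),
            force=np.full((2, 1), 150.0),
            sampling_rate=100.0, load_type="pinching",
        )
        frames = pl.simulate_pressure_frames(trial, geo, rng, quantize=True)
        assert frames[0].levels is not None
        assert frames[0].levels.min() >= 0
        assert frames[0].levels.max() <= 255
        assert np.all(frames[0].levels == np.round(frames[0].levels))

    def test_masked_sum_below_unmasked_sum(self, rng):
        geo = pl.default_film_geometry()
        trial = pl.TrialSeries(
            time=np.array([0.0, 0.01]),
            force=np.full((2, 1), 100.0),
            sampling_rate=100.0, load_type="pinching",
        )
        frames = pl.simulate_pressure_frames(trial, geo, rng,
                                             profile_sigma_mm=None,
                                             quantize=False)
        # sensel sum * area equals the force only before masking
        masked_force = frames[0].integral()
        assert masked_force < 100.0
        n_blind = (~geo.coverage).sum()
        expected = 100.0 * (geo.rows * geo.cols - n_blind) / (geo.rows * geo.cols)
        assert masked_force == pytest.approx(expected, rel=1e-9)


class TestReproducibilityAndIO:
    def test_staircase_bit_reproducible(self):
        cfg = pl.ProtocolConfig(contact_stiffness=3e4)
        a = pl.simulate_pendulum_staircase(150.0, cfg, np.random.default_rng(9))
        b = pl.simulate_pendulum_staircase(150.0, cfg, np.random.default_rng(9))
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            for ta, tb in zip(sa, sb):
                np.testing.assert_array_equal(ta.force, tb.force)

    def test_trial_csv_roundtrip(self, rng, tmp_path):
        cfg = pl.ProtocolConfig(contact_stiffness=5e4)
        trial = pl.simulate_algometer_trial(40.0, cfg, rng)
        trial.subject_id = "S001"
        trial.body_location_id = 12
        path = tmp_path / "trial.csv"
        write_trial(trial, path)
        back = read_trial(path)
        np.testing.assert_allclose(back.force, trial.force, atol=1e-5)
        assert back.event_index == trial.event_index
        assert back.subject_id == "S001"
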