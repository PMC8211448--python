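import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsgc_occlusion import (
    RegionResponse,
    TrialBlock,
    baseline_stats,
    detect_offset,
    detect_onset,
    dff,
    fit_rectified_sine,
    make_fluorescence_trace,
    make_trial_block,
    psth,
    quality_index,
    rectified_sine_rate,
    rsi,
    tuning_stats,
)


class TestPsth:
    def test_single_spike_rate(self):
        trials = np.zeros((1, 10))
        trials[0, 4] = 1
        assert psth(trials, 0.025)[4] == pytest.approx(40.0)

    def test_empty_trials(self):
        np.testing.assert_allclose(psth(np.zeros((3, 8)), 0.025), 0.0)

    def test_averaging_identity(self):
        one = np.arange(12.0)[None, :]
        k = np.repeat(one, 5, axis=0)
        np.testing.assert_allclose(psth(k, 0.025), psth(one, 0.025))

    def test_invalid_bin(self):
        with pytest.raises(ValueError):
            psth(np.zeros((1, 4)), 0.0)


class TestOnsetOffsetDetection:
    def test_step_onset(self):
        rate = np.zeros(30)
        rate[12:20] = 50.0
        assert detect_onset(rate, baseline_rate=0.0, baseline_sd=1.0) == 12

    def test_isolated_bin_rejected(self):
        rate = np.zeros(30)
        rate[12] = 50.0
        assert detect_onset(rate, 0.0, 1.0) is None

    def test_all_baseline_none(self):
        assert detect_onset(np.zeros(30), 0.0, 1.0) is None

    def test_rectangular_offset(self):
        rate = np.zeros(30)
        rate[10:21] = 50.0
        assert detect_offset(rate, 0.0, 1.0) == 20

    def test_trailing_isolated_bin_fails_two_of_three(self):
        rate = np.zeros(40)
        rate[10:21] = 50.0
        rate[30] = 50.0
        assert detect_offset(rate, 0.0, 1.0) == 20

    def test_translation_equivariance(self):
        rate = np.zeros(60)
        rate[20:30] = 40.0
        for shift in (3, 7):
            shifted = np.roll(rate, shift)
            assert detect_onset(shifted, 0.0, 1.0) == detect_onset(rate, 0.0, 1.0) + shift
            assert detect_offset(shifted, 0.0, 1.0) == detect_offset(rate, 0.0, 1.0) + shift

    def test_duration_recovery_on_noiseless_sine(self):
        bin_width = 0.025
        t = (np.arange(120) + 0.5) * bin_width
        rate = rectified_sine_rate(t, 40.0, 0.8, 0.9, 0.0)
        on = detect_onset(rate, 0.0, 0.5)
        off = detect_offset(rate, 0.0, 0.5)
        duration = (off - on + 1) * bin_width
        assert duration == pytest.approx(0.9, abs=2 * bin_width)


class TestSineFit:
    def test_noiseless_roundtrip(self):
        bin_width = 0.025
        t = (np.arange(120) + 0.5) * bin_width
        rate = rectified_sine_rate(t, 35.0, 0.7, 0.85, 0.0)
        fit = fit_rectified_sine(rate, bin_width)
        assert fit.converged
        assert fit.peak_rate == pytest.approx(35.0, rel=0.02)
        assert fit.onset == pytest.approx(0.7, abs=bin_width)
        assert fit.duration == pytest.approx(0.85, abs=bin_width)

    def test_amplitude_scaling(self):
        bin_width = 0.025
        t = (np.arange(120) + 0.5) * bin_width
        rate = rectified_sine_rate(t, 20.0, 0.7, 0.85, 0.0)
        f1 = fit_rectified_sine(rate, bin_width)
        f2 = fit_rectified_sine(3 * rate, bin_width)
        assert f2.peak_rate == pytest.approx(3 * f1.peak_rate, rel=0.01)
        assert f2.onset == pytest.approx(f1.onset, abs=1e-3)
        assert f2.duration == pytest.approx(f1.duration, rel=0.01)

    def test_recovery_under_count_noise(self):
        """Monte-Carlo: 6-trial PSTHs with variance-0.4 count noise recover the
        generator parameters within 10% at peak 40 Hz."""
        errors = []
        for rep in range(100):
            block, truth = make_trial_block(
                peak_rate=40.0, onset=0.8, duration=0.9, n_trials=6, seed=1000 + rep
            )
            fit = fit_rectified_sine(psth(block), block.bin_width)
            errors.append(abs(fit.peak_rate - 40.0) / 40.0)
            assert fit.onset == pytest.approx(0.8, abs=0.1)
            assert fit.duration == pytest.approx(0.9, abs=0.15)
        assert np.median(errors) < 0.10

    def test_flat_input_raises(self):
        with pytest.raises(ValueError):
            fit_rectified_sine(np.zeros(50), 0.025)


class TestRsi:
    @pytest.mark.parametrize(
        "mx,opp,expected", [(5.0, 5.0, 0.0), (5.0, 0.0, 1.0), (3.0, 1.0, 0.5)]
    )
    def test_closed_form_cases(self, mx, opp, expected):
        assert rsi(RegionResponse(mx, opp)) == pytest.approx(expected)

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_swap(self, a, b):
        if a + b == 0:
            return
        assert rsi(RegionResponse(a, b)) == pytest.approx(-rsi(RegionResponse(b, a)))

    def test_both_zero_raises(self):
        with pytest.raises(ValueError):
            rsi(RegionResponse(0.0, 0.0))


class TestTuningStats:
    def test_single_direction_response(self):
        resp = np.zeros(8)
        resp[2] = 10.0  # 90 deg
        ts = tuning_stats(resp)
        assert ts.dsi == pytest.approx(1.0)
        assert ts.preferred_direction == pytest.approx(90.0)
        assert ts.circular_variance == pytest.approx(0.0)

    def test_uniform_responses_flagged(self):
        ts = tuning_stats(np.full(8, 3.0))
        assert ts.dsi == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(ts.preferred_direction)
        assert ts.circular_variance == pytest.approx(1.0)

    def test_opposite_directions_cancel(self):
        resp = np.zeros(8)
        resp[0] = 10.0
        resp[4] = 10.0
        assert tuning_stats(resp).dsi == pytest.approx(0.0, abs=1e-12)

    def test_angular_deviation_definition(self):
        resp = np.zeros(8)
        resp[0] = 5.0
        resp[1] = 5.0
        ts = tuning_stats(resp)
        assert ts.angular_deviation == pytest.approx(
            np.rad2deg(np.sqrt(2 * ts.circular_variance))
        )

    def test_uniform_offset_strictly_decreases_dsi(self):
        rng = np.random.default_rng(7)
        resp = rng.gamma(2.0, 5.0, 8)
        base = tuning_stats(resp).dsi
        assert tuning_stats(resp + 10.0).dsi < base

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            tuning_stats(np.zeros(8))


class TestQualityIndex:
    def test_identical_trials_is_one(self):
        trial = np.sin(np.linspace(0, 3, 50)) ** 2
        assert quality_index(np.tile(trial, (4, 1))) == pytest.approx(1.0)

    def test_pure_noise_approaches_one_over_n(self):
        """For independent noise trials QI -> 1/N (variance of a mean)."""
        rng = np.random.default_rng(11)
        for n in (3, 8):
            qi = quality_index(rng.normal(0, 1, (n, 20000)))
            assert qi == pytest.approx(1.0 / n, rel=0.15)

    def test_gate_at_threshold(self):
        rng = np.random.default_rng(12)
        trial = np.sin(np.linspace(0, 3, 200)) ** 2
        good = np.tile(trial, (4, 1))
        noise = rng.normal(0, 1, (4, 200))
        assert quality_index(good) >= 0.45
        assert quality_index(noise) < 0.45

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            quality_index(np.ones((3, 10)))
        with pytest.raises(ValueError):
            quality_index(np.zeros((1, 10)))


class TestDff:
    def test_flat_trace_is_zero(self):
        trace, mask, _ = make_fluorescence_trace(transient_starts=(), noise_sd=0.0, bleach_tau=1e9, f0_amplitude=0.0)
        out = dff(trace, mask, sample_dt=0.05)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_doubled_fluorescence_is_one(self):
        n = 200
        trace = np.full(n, 100.0)
        mask = np.zeros(n, dtype=bool)
        mask[:50] = True
        trace[100:150] = 200.0
        out = dff(trace, mask, sample_dt=0.05, smooth_window=1)
        assert out[120] == pytest.approx(1.0, abs=1e-6)

    def test_bleaching_roundtrip_recovers_transients(self):
        trace, mask, truth = make_fluorescence_trace(noise_sd=0.0)
        out = dff(trace, mask, sample_dt=truth.params["sample_dt"])
        assert out.max() == pytest.approx(truth.params["transient_amplitude"], rel=0.05)

    def test_recovery_under_noise(self):
        trace, mask, truth = make_fluorescence_trace(noise_sd=0.05 * 50.0, seed=5)
        out = dff(trace, mask, sample_dt=truth.params["sample_dt"])
        assert out.max() == pytest.approx(truth.params["transient_amplitude"], rel=0.25)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dff(np.ones(10), np.ones(5, dtype=bool))


class TestTrialBlock:
    def test_csv_roundtrip(self, tmp_path):
        block, _ = make_trial_block(30.0, 0.5, 0.8, n_trials=3, seed=0)
        path = tmp_path / "block.csv"
        block.to_csv(path)
        back = TrialBlock.from_csv(path)
        np.testing.assert_allclose(back.trials, block.trials)
        assert back.bin_width == block.bin_width
        assert back.baseline_interval == block.baseline_interval

    def test_baseline_stats_from_silent_interval(self):
        block, _ = make_trial_block(40.0, 1.0, 0.8, n_trials=5, baseline_rate=0.0, seed=1)
        rate, sd = baseline_stats(block)
        assert rate == 0.0 and sd == 0.0
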