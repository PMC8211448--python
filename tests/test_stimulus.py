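import numpy as np
import pytest

from dsgc_occlusion import (
    AGAINST_MOTION,
    MODE_NULL_OCCLUSION,
    MODE_PREFERRED_FULLFIELD,
    MODE_PREFERRED_POST_EMERGENCE,
    MODE_SILENT,
    WITH_MOTION,
    ExperimentConfig,
    GeometryConfig,
    Occluder,
    PopulationActivity,
    ResponseConfig,
    build_mosaic,
    classify_response_mode,
    draw_population_params,
    make_stimulus,
    run_block,
    sample_counts,
    simulate_trial,
)
from dsgc_occlusion.stimulus import _mean_rates


@pytest.fixture(scope="module")
def scene():
    mosaic = build_mosaic(GeometryConfig(), seed=21)
    params = draw_population_params(mosaic, ResponseConfig(), speed=330.0, seed=22)
    stimulus = make_stimulus(mosaic, 330.0)
    occluder = Occluder(center=(1800.0, 800.0), diameter=220.0)
    return mosaic, params, stimulus, occluder


class TestSampleCounts:
    def test_variance_matches_law_above_floor(self, rng):
        draws = sample_counts(np.full(100_000, 4.0), 0.4, rng, integerize=False)
        assert draws.var() == pytest.approx(0.4, abs=0.02)
        assert draws.mean() == pytest.approx(4.0, abs=0.02)

    def test_integerized_counts_are_nonnegative_integers(self, rng):
        draws = sample_counts(np.full(10_000, 0.5), 0.4, rng)
        assert np.all(draws >= 0)
        np.testing.assert_array_equal(draws, np.rint(draws))


class TestClassifyModes:
    def test_fullfield_modes(self, scene):
        mosaic, params, stimulus, _ = scene
        modes = classify_response_mode(mosaic, params, stimulus)
        with_motion = mosaic.mask(WITH_MOTION)
        assert np.all(modes.mode[with_motion] == MODE_PREFERRED_FULLFIELD)
        assert np.all(modes.mode[~with_motion] == MODE_SILENT)
        assert np.all(np.isnan(modes.t_on[~with_motion]))
        assert modes.emergence_time is None

    def test_occluded_modes_near_and_far(self, scene):
        mosaic, params, stimulus, occluder = scene
        modes = classify_response_mode(mosaic, params, stimulus, occluder)
        assert modes.emergence_time == pytest.approx(stimulus.arrival_time(occluder.x_exit))
        label_x = mosaic.position_label[:, 0]
        covers = np.abs(label_x - occluder.x_exit) <= mosaic.rf_width
        against = mosaic.mask(AGAINST_MOTION)
        # null-occlusion responses exactly where the RF covers the exit
        assert np.all(modes.mode[against & covers] == MODE_NULL_OCCLUSION)
        assert np.all(modes.mode[against & ~covers] == MODE_SILENT)
        # motion-aligned cells under the occluder resume firing post-emergence
        burst = modes.mode == MODE_PREFERRED_POST_EMERGENCE
        assert np.any(burst)
        assert np.all(covers[burst])
        # cells far from the occluder keep the full-field assignment
        far = np.abs(mosaic.position[:, 0] - 1800.0) > 600.0
        ff_modes = classify_response_mode(mosaic, params, stimulus)
        np.testing.assert_array_equal(modes.mode[far], ff_modes.mode[far])

    def test_no_evoked_spikes_before_emergence_for_occlusion_modes(self, scene):
        mosaic, params, stimulus, occluder = scene
        modes = classify_response_mode(mosaic, params, stimulus, occluder)
        occl = np.isin(modes.mode, [MODE_NULL_OCCLUSION, MODE_PREFERRED_POST_EMERGENCE])
        assert np.all(modes.t_on[occl] >= modes.emergence_time - 1e-12)

    def test_truncation_at_entry(self, scene):
        """In occluded runs no cell's evoked rate survives into the hidden
        epoch: ongoing responses are cut when the edge disappears."""
        mosaic, params, stimulus, occluder = scene
        modes = classify_response_mode(mosaic, params, stimulus, occluder)
        t_entry = float(stimulus.arrival_time(occluder.x_entry))
        t_em = modes.emergence_time
        times = np.arange(t_entry + 0.005, t_em - 0.005, 0.01)
        rates = _mean_rates(modes, times, baseline=0.0)
        assert rates.max() == 0.0

    def test_occluder_outside_mosaic_warns(self, scene):
        mosaic, params, stimulus, _ = scene
        far = Occluder(center=(50_000.0, 50_000.0), diameter=220.0)
        with pytest.warns(UserWarning):
            classify_response_mode(mosaic, params, stimulus, far)


class TestSimulateTrial:
    def test_zero_peak_zero_baseline_gives_silence(self, scene):
        mosaic, params, stimulus, _ = scene
        import dataclasses

        silent = dataclasses.replace(
            params, peak_fullfield=np.zeros_like(params.peak_fullfield),
            peak_occlusion_null=np.zeros_like(params.peak_occlusion_null), baseline_rate=0.0,
        )
        act = simulate_trial(mosaic, silent, stimulus, seed=0)
        assert act.spike_counts.sum() == 0

    def test_noiseless_counts_follow_rate(self, scene):
        mosaic, params, stimulus, _ = scene
        act = simulate_trial(mosaic, params, stimulus, noise_var=0.0, seed=0)
        expected = np.rint(np.clip(act.mean_rates, 0, None) * act.bin_width)
        np.testing.assert_array_equal(act.spike_counts, expected)

    def test_counts_are_nonnegative_integers(self, scene):
        mosaic, params, stimulus, occluder = scene
        act = simulate_trial(mosaic, params, stimulus, occluder=occluder, seed=3)
        assert act.spike_counts.dtype.kind == "i"
        assert act.spike_counts.min() >= 0

    def test_baseline_only_bins_have_poisson_mean(self, scene):
        mosaic, params, stimulus, _ = scene
        import dataclasses

        quiet = dataclasses.replace(
            params, peak_fullfield=np.zeros_like(params.peak_fullfield), baseline_rate=2.0
        )
        act = simulate_trial(mosaic, quiet, stimulus, seed=4)
        mean_count = act.spike_counts.mean()
        assert mean_count == pytest.approx(2.0 * act.bin_width, rel=0.05)

    def test_population_peak_tracks_edge_linearly(self, scene):
        """Noiseless full-field run: the time of peak summed rate advances
        linearly with edge position at slope 1/speed (R^2 > 0.99)."""
        mosaic, params, stimulus, _ = scene
        modes = classify_response_mode(mosaic, params, stimulus)
        times = np.arange(stimulus.t_start, stimulus.t_end, 0.01)
        rates = _mean_rates(modes, times + 0.005, 0.0)
        # per-cell peak time vs label position of responding cells
        responding = modes.peak_rate > 1.0
        peak_times = times[np.argmax(rates[responding], axis=1)]
        label_x = mosaic.position_label[responding, 0]
        interior = (label_x > np.percentile(label_x, 5)) & (label_x < np.percentile(label_x, 95))
        coeffs = np.polyfit(label_x[interior], peak_times[interior], 1)
        pred = np.polyval(coeffs, label_x[interior])
        ss_res = np.sum((peak_times[interior] - pred) ** 2)
        ss_tot = np.sum((peak_times[interior] - peak_times[interior].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99
        assert coeffs[0] == pytest.approx(1 / 330.0, rel=0.1)


class TestRunBlock:
    def test_paired_design_and_counts(self, small_config):
        out = run_block(small_config, 330.0, 0.0, block_seed=5, n_reps=3)
        assert len(out["fullfield"]) == 3 and len(out["occluded"]) == 3
        # same mosaic and parameter draw in both conditions (paired design)
        assert out["fullfield"][0].n_cells == out["occluded"][0].n_cells == 300
        # per-trial noise differs within a condition
        assert not np.array_equal(
            out["fullfield"][0].spike_counts, out["fullfield"][1].spike_counts
        )

    def test_block_seed_reproducibility(self, small_config):
        a = run_block(small_config, 330.0, 0.0, block_seed=6, n_reps=2)
        b = run_block(small_config, 330.0, 0.0, block_seed=6, n_reps=2)
        np.testing.assert_array_equal(a["mosaic"].position, b["mosaic"].position)
        np.testing.assert_array_equal(a["params"].onset_offset, b["params"].onset_offset)
        np.testing.assert_array_equal(
            a["occluded"][1].spike_counts, b["occluded"][1].spike_counts
        )

    def test_invalid_reps(self, small_config):
        with pytest.raises(ValueError):
            run_block(small_config, 330.0, 0.0, block_seed=0, n_reps=0)


def test_activity_csv_roundtrip(tmp_path, small_config):
    out = run_block(small_config, 660.0, 0.1, block_seed=9, n_reps=1)
    act = out["occluded"][0]
    path = tmp_path / "trial.csv"
    act.to_csv(path)
    back = PopulationActivity.from_csv(path)
    np.testing.assert_array_equal(back.spike_counts, act.spike_counts)
    np.testing.assert_allclose(back.times, act.times)
    assert back.emergence_time == pytest.approx(act.emergence_time)
    assert back.stimulus.speed == act.stimulus.speed
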