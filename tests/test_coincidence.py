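import numpy as np
import pytest

from dsgc_occlusion import (
    DoGFilter,
    ExperimentConfig,
    Occluder,
    classify_trials,
    detector_score,
    fit_dog_filter,
    monitored_cells,
    roc_sweep,
    run_block,
    run_roc_experiment,
    summed_monitor_rate,
)


def dog_curve(t, ac, asur, t0, sc, ss):
    return ac * np.exp(-((t - t0) ** 2) / (2 * sc**2)) - asur * np.exp(-((t - t0) ** 2) / (2 * ss**2))


class TestDoGFit:
    def test_recovers_self(self):
        """A template that is itself a (balanced) DoG is a fixed point of the fit."""
        t = np.arange(-0.5, 0.5, 0.01)
        truth = dog_curve(t, 10.0, 10.0 * 0.05 / 0.15, 0.02, 0.05, 0.15)
        filt = fit_dog_filter(truth, 0.01, t=t)
        assert filt.residual < 0.01 * 10.0
        assert filt.sd_center == pytest.approx(0.05, rel=0.05)
        assert filt.sd_surround == pytest.approx(0.15, rel=0.05)
        assert filt.amp_center == pytest.approx(10.0, rel=0.05)

    def test_halfsine_template_width_sanity_band(self):
        """Fitting a half-sine transient of duration d: brute-force grid search
        over DoG widths is the oracle for the best-fit center SD."""
        d = 0.3
        t = np.arange(-0.5, 0.5, 0.01)
        template = np.where((t >= 0) & (t <= d), np.sin(np.pi * np.clip(t, 0, d) / d), 0.0) * 20.0

        # oracle: grid over (sc, ss, t0), amplitude solved by least squares
        best = (np.inf, None)
        for sc in np.linspace(d / 8, d, 40):
            for ss_mult in np.linspace(1.05, 4.0, 20):
                for t0 in np.linspace(0.0, d, 15):
                    ss = sc * ss_mult
                    shape = dog_curve(t, 1.0, sc / ss, t0, sc, ss)
                    a = np.dot(shape, template) / np.dot(shape, shape)
                    resid = np.sum((a * shape - template) ** 2)
                    if resid < best[0]:
                        best = (resid, sc)
        filt = fit_dog_filter(template, 0.01, t=t)
        assert d / 6 <= filt.sd_center <= d / 2
        assert filt.sd_center == pytest.approx(best[1], abs=d / 8)

    def test_amplitude_scaling_linearity(self):
        t = np.arange(-0.5, 0.5, 0.01)
        template = np.exp(-(t**2) / (2 * 0.08**2)) * 5.0
        f1 = fit_dog_filter(template, 0.01, t=t)
        f3 = fit_dog_filter(3.0 * template, 0.01, t=t)
        assert f3.amp_center == pytest.approx(3.0 * f1.amp_center, rel=0.05)
        assert f3.sd_center == pytest.approx(f1.sd_center, rel=0.05)

    def test_flat_template_raises(self):
        with pytest.raises(ValueError):
            fit_dog_filter(np.zeros(100), 0.01)

    def test_invariants(self):
        with pytest.raises(ValueError):
            DoGFilter(amp_center=1.0, amp_surround=0.5, sd_center=0.2, sd_surround=0.1, t_center=0.0, dt=0.01)


class TestDetectorScore:
    def _filt(self):
        t = np.arange(-0.5, 0.5, 0.01)
        return fit_dog_filter(np.exp(-(t**2) / (2 * 0.06**2)), 0.01, t=t)

    def test_zero_input_zero_score(self):
        filt = self._filt()
        np.testing.assert_allclose(detector_score(np.zeros(300), filt, 0.01), 0.0)

    def test_delta_input_returns_time_reversed_taps(self):
        filt = self._filt()
        x = np.zeros(301)
        x[150] = 1.0
        score = detector_score(x, filt, 0.01)
        taps = filt.taps[::-1]
        k = len(taps) // 2
        np.testing.assert_allclose(score[150 - k : 150 - k + len(taps)], taps, atol=1e-12)

    def test_linearity_superposition(self):
        filt = self._filt()
        rng = np.random.default_rng(0)
        a, b = rng.random(400), rng.random(400)
        lhs = detector_score(2 * a + 3 * b, filt, 0.01)
        rhs = 2 * detector_score(a, filt, 0.01) + 3 * detector_score(b, filt, 0.01)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_bin_width_mismatch(self):
        with pytest.raises(ValueError):
            detector_score(np.zeros(10), self._filt(), 0.025)


class TestClassifyTrials:
    def test_threshold_extremes(self):
        score = np.array([0.0, 1.0, 5.0, 1.0, 0.0, 2.0, 0.0])
        win = np.array([False, True, True, True, False, False, False])
        hit, fa = classify_trials([score], -1.0, [win])
        assert hit[0]  # everything is one event overlapping the window
        hit, fa = classify_trials([score], 10.0, [win])
        assert not hit[0] and not fa[0]

    def test_event_overlap_semantics(self):
        score = np.array([0.0, 1.0, 5.0, 1.0, 0.0, 2.0, 0.0])
        win = np.array([False, True, True, True, False, False, False])
        hit, fa = classify_trials([score], 1.5, [win])
        assert hit[0]  # in-window event
        assert fa[0]  # the separate event at index 5 lies outside
        hit, fa = classify_trials([score], 3.0, [win])
        assert hit[0] and not fa[0]

    def test_fullfield_trials_every_event_is_false_alarm(self):
        score = np.array([0.0, 2.0, 0.0])
        win = np.array([False, True, False])
        hit, fa = classify_trials([score], 1.0, [win], occlusion_trials=False)
        assert not hit[0] and fa[0]


class TestRocSweep:
    def _make(self, occ_peak, ff_peak, n=20, seed=0):
        rng = np.random.default_rng(seed)
        occ, ff, owin, fwin = [], [], [], []
        win = np.zeros(100, dtype=bool)
        win[48:52] = True
        for _ in range(n):
            s = rng.normal(0, 1, 100)
            s[50] += occ_peak
            occ.append(s)
            owin.append(win)
            ff.append(rng.normal(0, 1, 100) + (ff_peak if ff_peak else 0))
            fwin.append(win)
        return occ, ff, owin, fwin

    def test_separated_scores_auc_one(self):
        occ, ff, ow, fw = self._make(occ_peak=50.0, ff_peak=0.0)
        res = roc_sweep(occ, ff, ow, fw)
        assert res.auc > 0.99
        assert res.accuracy == pytest.approx(1.0)

    def test_identical_distributions_chance(self):
        occ, ff, ow, fw = self._make(occ_peak=0.0, ff_peak=0.0, seed=3)
        res = roc_sweep(occ, ff, ow, fw)
        assert res.auc < 0.6  # no separable signal

    def test_hit_and_fullfield_fa_monotone_in_threshold(self):
        occ, ff, ow, fw = self._make(occ_peak=3.0, ff_peak=0.0, seed=5)
        res = roc_sweep(occ, ff, ow, fw)
        assert np.all(np.diff(res.hit_rate) <= 1e-12)
        ff_fa = np.array(
            [classify_trials(ff, t, fw, occlusion_trials=False)[1].mean() for t in res.thresholds]
        )
        assert np.all(np.diff(ff_fa) <= 1e-12)

    def test_empty_trial_set_raises(self):
        occ, ff, ow, fw = self._make(1.0, 0.0)
        with pytest.raises(ValueError):
            roc_sweep([], ff, [], fw)


@pytest.mark.parametrize("baseline", [0.0, 1.0])
def test_occlusion_score_peaks_inside_detection_window(baseline):
    """Simulated occlusion trials: the matched-filter output must peak within
    the 125 ms window around emergence."""
    cfg = ExperimentConfig(seed=3)
    block = run_block(cfg, 330.0, baseline, block_seed=8, n_reps=4)
    mosaic, occluder = block["mosaic"], block["occluder"]
    t_em = block["occluded"][0].emergence_time
    sub = monitored_cells(mosaic, occluder, cfg.coincidence.monitor_radius_um)
    times = block["occluded"][0].times
    rates = [summed_monitor_rate(a, sub) for a in block["occluded"]]
    template = np.mean(rates, axis=0)
    near = np.abs(times + 0.005 - t_em) <= 0.5
    filt = fit_dog_filter(template[near] - np.median(template), 0.01, t=times[near] + 0.005 - t_em)
    for rate in rates:
        score = detector_score(rate, filt, 0.01)
        t_peak = times[np.argmax(score)] + 0.005
        assert abs(t_peak - t_em) <= 0.0625


def test_roc_experiment_auc_non_increasing_with_baseline(small_config):
    small_config.geometry.n_cells = 1000
    results = run_roc_experiment(
        small_config, baseline_rates=(0.0, 1.0, 50.0), n_trials_per_condition=10
    )
    aucs = [r.auc for r in results]
    assert all(a >= b - 0.05 for a, b in zip(aucs, aucs[1:]))
    assert results[0].accuracy > 0.9
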