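"""Difference-of-Gaussian coincidence detector for interrupted motion.

The synchronous preferred+null transient at the occluder leaves a sharp bump
in the summed firing rate of the against-motion cells near the occluder.  A
difference-of-Gaussian (DoG) temporal filter fit to the trial-averaged
null-direction occlusion response is convolved with that summed rate; an
occlusion event is declared whenever the filter output crosses a threshold
inside a 125 ms window around the edge's emergence.  Above-threshold
crossings outside the window count as false alarms; sweeping the threshold
yields the ROC and its area quantifies detectability at each baseline-firing
level.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geometry import AGAINST_MOTION, CellMosaic
from .stimulus import Occluder, PopulationActivity

__all__ = [
    "DoGFilter",
    "RocResult",
    "fit_dog_filter",
    "monitored_cells",
    "summed_monitor_rate",
    "detector_score",
    "classify_trials",
    "roc_sweep",
]


@dataclass
class DoGFilter:
    """Difference-of-Gaussian temporal filter sampled at the activity bin width."""

    amp_center: float
    amp_surround: float
    sd_center: float  # s
    sd_surround: float  # s
    t_center: float  # s, peak location within the support
    dt: float  # s
    halfwidth: float = 0.5  # s, support is [-halfwidth, +halfwidth]
    residual: float = float("nan")  # RMS residual of the template fit

    def __post_init__(self) -> None:
        if not 0 < self.sd_center < self.sd_surround:
            raise ValueError("require sd_surround > sd_center > 0")

    @property
    def support(self) -> np.ndarray:
        return np.arange(-self.halfwidth, self.halfwidth + self.dt / 2.0, self.dt)

    @property
    def taps(self) -> np.ndarray:
        return self.evaluate(self.support)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float) - self.t_center
        return self.amp_center * np.exp(-(t**2) / (2 * self.sd_center**2)) - self.amp_surround * np.exp(
            -(t**2) / (2 * self.sd_surround**2)
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.support, "tap": self.taps}).to_csv(path, index=False)


def _dog(t: np.ndarray, p: np.ndarray, balanced: bool) -> np.ndarray:
    if balanced:
        ac, t0, sc, dsd = p
        ss = sc + dsd
        asur = ac * sc / ss  # equal areas: the filter integrates to ~0
    else:
        ac, asur, t0, sc, dsd = p
        ss = sc + dsd
    return ac * np.exp(-((t - t0) ** 2) / (2 * sc**2)) - asur * np.exp(-((t - t0) ** 2) / (2 * ss**2))


def fit_dog_filter(
    template: np.ndarray,
    dt: float,
    t: np.ndarray | None = None,
    halfwidth: float = 0.5,
    balanced: bool = True,
) -> DoGFilter:
    """Least-squares DoG fit to a (trial-averaged) response template.

    ``template`` is a firing-rate trace with one dominant transient; ``t`` its
    time base (defaults to 0, dt, 2dt, ...).  With ``balanced`` (default) the
    center and surround areas are constrained equal, so the filter integrates
    to ~zero: its matched output then has a narrow positive core flanked by
    negative lobes, which is what lets a 125 ms window isolate the event.  The
    fit is returned with its RMS residual; a flat template raises, since there
    is nothing to fit.
    """
    template = np.asarray(template, dtype=float)
    if t is None:
        t = np.arange(template.size) * dt
    t = np.asarray(t, dtype=float)
    span = float(template.max() - template.min())
    if span <= 0 or not np.isfinite(span):
        raise ValueError("template is flat; cannot fit a DoG filter")

    t_peak = float(t[np.argmax(template)])
    # crude width guess: half-max extent of the dominant transient
    above = template > template.min() + span / 2.0
    width0 = max(dt, float(above.sum()) * dt / 2.355)
    # the surround must live inside the filter support, else "balanced"
    # degenerates to a flat offset and the output loses its negative lobes
    sd_cap = halfwidth / 2.0
    width0 = min(width0, sd_cap / 2.0)
    if balanced:
        p0 = np.array([span, t_peak, width0, width0])
        lb = np.array([0.0, t.min() - 1.0, dt / 4.0, dt / 4.0])
        ub = np.array([100 * span, t.max() + 1.0, sd_cap, sd_cap])
    else:
        p0 = np.array([span, span * 0.3, t_peak, width0, width0])
        lb = np.array([0.0, 0.0, t.min() - 1.0, dt / 4.0, dt / 4.0])
        ub = np.array([100 * span, 100 * span, t.max() + 1.0, sd_cap, sd_cap])
    sol = least_squares(lambda p: _dog(t, p, balanced) - template, p0, bounds=(lb, ub))
    if balanced:
        ac, t0, sc, dsd = sol.x
        asur = ac * sc / (sc + dsd)
    else:
        ac, asur, t0, sc, dsd = sol.x
    resid = float(np.sqrt(np.mean(sol.fun**2)))
    return DoGFilter(
        amp_center=float(ac),
        amp_surround=float(asur),
        sd_center=float(sc),
        sd_surround=float(sc + dsd),
        t_center=float(t0),
        dt=dt,
        halfwidth=halfwidth,
        residual=resid,
    )


def monitored_cells(mosaic: CellMosaic, occluder: Occluder, radius: float = 220.0) -> np.ndarray:
    """Against-motion (null-responding) cells within ``radius`` of the occluder center."""
    dist = np.linalg.norm(mosaic.position - np.asarray(occluder.center), axis=1)
    return mosaic.mask(AGAINST_MOTION) & (dist <= radius)


def summed_monitor_rate(activity: PopulationActivity, subset: np.ndarray) -> np.ndarray:
    """Summed firing rate (Hz) of the monitored subset per time bin."""
    return activity.rates_hz()[subset].sum(axis=0)


def detector_score(rate: np.ndarray, filt: DoGFilter, dt: float) -> np.ndarray:
    """Matched-filter output: the summed rate convolved with the time-reversed
    DoG taps (equivalently, correlated with the taps), on the same time base.

    The filter is fit on a time axis referenced to the emergence instant, so
    its output peaks *at* the occlusion event rather than a response-latency
    later; a delta-spike input returns the time-reversed filter.
    """
    if abs(dt - filt.dt) > 1e-12:
        raise ValueError("filter taps and activity bin width differ")
    return np.convolve(np.asarray(rate, dtype=float), filt.taps[::-1], mode="same")


def classify_trials(
    scores: Sequence[np.ndarray],
    threshold: float,
    window_masks: Sequence[np.ndarray],
    occlusion_trials: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial detection outcome at one threshold.

    Detections are *events*: contiguous runs of above-threshold filter output.
    On occlusion trials, an event overlapping the detection window is the
    correct detection (hit) and events lying entirely outside it are false
    alarms — the shoulders of one broad detection event do not count against
    it.  On full-field trials there is no event to detect, so every
    above-threshold event is a false alarm.  Returns (hit, false_alarm)
    boolean arrays over trials.
    """
    hits, fas = [], []
    for score, win in zip(scores, window_masks):
        above = score > threshold
        if not np.any(above):
            hits.append(False)
            fas.append(False)
            continue
        # label contiguous above-threshold segments
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(above.size)
        overlaps = [bool(np.any(win[s:e])) for s, e in zip(starts, ends)]
        if occlusion_trials:
            hits.append(any(overlaps))
            fas.append(any(not o for o in overlaps))
        else:
            hits.append(False)
            fas.append(True)  # any detection on a no-event trial is false
    return np.asarray(hits), np.asarray(fas)


@dataclass
class RocResult:
    """Threshold sweep of the coincidence detector."""

    thresholds: np.ndarray
    hit_rate: np.ndarray  # P(in-window crossing | occlusion trial)
    false_alarm_rate: np.ndarray  # P(outside-window crossing | any trial)
    auc: float
    accuracy: float  # occlusion-trial hit rate at the Youden-optimal threshold
    operating_threshold: float
    baseline_hz: float = float("nan")
    meta: dict[str, Any] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"threshold": self.thresholds, "hit_rate": self.hit_rate, "false_alarm_rate": self.false_alarm_rate}
        ).to_csv(path, index=False)

    def summary(self) -> dict[str, float]:
        return {"auc": self.auc, "accuracy": self.accuracy, "baseline_hz": self.baseline_hz}


def roc_sweep(
    occlusion_scores: Sequence[np.ndarray],
    fullfield_scores: Sequence[np.ndarray],
    occlusion_windows: Sequence[np.ndarray],
    fullfield_windows: Sequence[np.ndarray],
    thresholds: np.ndarray | None = None,
    n_thresholds: int = 200,
    baseline_hz: float = float("nan"),
) -> RocResult:
    """ROC over a threshold sweep, trapezoidal AUC and Youden-point accuracy.

    Hits are scored on occlusion trials (in-window crossings); false alarms on
    all trials (outside-window crossings).  The operating point maximizes
    Youden's J = hit_rate - false_alarm_rate.
    """
    if len(occlusion_scores) == 0 or len(fullfield_scores) == 0:
        raise ValueError("both trial sets must be non-empty")
    if thresholds is None:
        # hit/false-alarm status changes at per-trial extrema of the score,
        # so sweep those critical values plus pooled quantiles for coverage
        crit = []
        for scores, wins in ((occlusion_scores, occlusion_windows), (fullfield_scores, fullfield_windows)):
            for s, w in zip(scores, wins):
                crit.append(float(s.max()))
                if np.any(w):
                    crit.append(float(s[w].max()))
                if np.any(~w):
                    crit.append(float(s[~w].max()))
        pooled = np.concatenate([np.ravel(s) for s in list(occlusion_scores) + list(fullfield_scores)])
        crit.extend(np.quantile(pooled, np.linspace(0.0, 1.0, 101)).tolist())
        thresholds = np.unique(np.asarray(crit))
        if thresholds.size < 2:
            raise ValueError("degenerate score range; cannot sweep thresholds")
        eps = 1e-9 * max(1.0, float(np.abs(thresholds).max()))
        thresholds = np.concatenate([[thresholds[0] - eps], thresholds - eps / 2.0, [thresholds[-1] + eps]])
        if thresholds.size > n_thresholds:
            idx = np.unique(np.linspace(0, thresholds.size - 1, n_thresholds).astype(int))
            thresholds = thresholds[idx]
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size < 2:
        raise ValueError("threshold sweep needs at least two thresholds")

    hit_rate = np.empty(thresholds.size)
    fa_rate = np.empty(thresholds.size)
    for k, thr in enumerate(thresholds):
        occ_hit, occ_fa = classify_trials(occlusion_scores, thr, occlusion_windows, occlusion_trials=True)
        _, ff_fa = classify_trials(fullfield_scores, thr, fullfield_windows, occlusion_trials=False)
        hit_rate[k] = occ_hit.mean()
        fa_rate[k] = np.concatenate([occ_fa, ff_fa]).mean()

    order = np.lexsort((hit_rate, fa_rate))
    fa_sorted = np.concatenate([[0.0], fa_rate[order], [1.0]])
    hit_sorted = np.concatenate([[0.0], hit_rate[order], [1.0]])
    auc = float(np.trapezoid(hit_sorted, fa_sorted))

    youden = hit_rate - fa_rate
    # maximize J; break ties toward the lower false-alarm operating point
    best = int(np.lexsort((fa_rate, -youden))[0])
    return RocResult(
        thresholds=thresholds,
        hit_rate=hit_rate,
        false_alarm_rate=fa_rate,
        auc=auc,
        accuracy=float(hit_rate[best]),
        operating_threshold=float(thresholds[best]),
        baseline_hz=baseline_hz,
        meta={"n_occlusion": len(occlusion_scores), "n_fullfield": len(fullfield_scores)},
    )
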