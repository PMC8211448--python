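"""Recording-analysis metrics: PSTH, onset/offset detection, sine fits,
response symmetry, circular tuning statistics, fluorescence dF/F0 and the
response quality index.

These are the analysis procedures applied to (synthetic) trial blocks: spikes
are binned at 25 ms, onsets detected where the rate first exceeds baseline +
4 SD in two consecutive bins, offsets by the same scan run backwards with a
2-of-3 rule, and a rectified sine is fit to the PSTH.  Direction tuning uses
resultant-vector statistics (DSI, vector-sum angle, circular variance and the
angular deviation sqrt(2 CV)).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .responses import rectified_sine_rate

__all__ = [
    "TrialBlock",
    "RegionResponse",
    "psth",
    "baseline_stats",
    "detect_onset",
    "detect_offset",
    "fit_rectified_sine",
    "SineFit",
    "rsi",
    "tuning_stats",
    "TuningStats",
    "quality_index",
    "dff",
]


@dataclass
class TrialBlock:
    """Repetition x time matrix of spike counts (or fluorescence samples)."""

    trials: np.ndarray  # (n_trials, n_bins)
    bin_width: float  # s
    baseline_interval: tuple[float, float] = (0.0, 0.0)  # s, pre-stimulus
    direction_labels: np.ndarray | None = None  # deg per sweep, tuning blocks
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.trials.shape[0] < 1:
            raise ValueError("TrialBlock needs at least one trial")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.trials.shape[1]) * self.bin_width

    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV (trial, bin_start_s, value) + JSON header."""
        path = Path(path)
        n_t, n_b = self.trials.shape
        df = pd.DataFrame(
            {
                "trial": np.repeat(np.arange(n_t), n_b),
                "bin_start_s": np.tile(self.times, n_t),
                "value": self.trials.ravel(),
            }
        )
        df.to_csv(path, index=False)
        header = {
            "bin_width": self.bin_width,
            "baseline_interval": list(self.baseline_interval),
            "direction_labels": None if self.direction_labels is None else list(map(float, self.direction_labels)),
            **self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialBlock":
        path = Path(path)
        df = pd.read_csv(path)
        header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        trials = df.pivot(index="trial", columns="bin_start_s", values="value").to_numpy()
        dirs = header.get("direction_labels")
        return cls(
            trials=trials,
            bin_width=header["bin_width"],
            baseline_interval=tuple(header["baseline_interval"]),
            direction_labels=None if dirs is None else np.asarray(dirs, dtype=float),
        )


@dataclass
class RegionResponse:
    """Responses in the maximally activated RF region and the opposite one."""

    max_response: float
    opp_response: float

    def __post_init__(self) -> None:
        if self.max_response < 0 or self.opp_response < 0:
            raise ValueError("region responses must be non-negative")


def psth(trials: np.ndarray | TrialBlock, bin_width: float | None = None) -> np.ndarray:
    """Trial-averaged firing rate (Hz) per bin: mean counts / bin width."""
    if isinstance(trials, TrialBlock):
        bin_width = trials.bin_width
        trials = trials.trials
    if bin_width is None or bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return np.atleast_2d(np.asarray(trials, dtype=float)).mean(axis=0) / bin_width


def baseline_stats(block: TrialBlock) -> tuple[float, float]:
    """(baseline rate, baseline SD) in Hz from the designated silent interval.

    Baseline rate follows the recording convention: the maximum per-bin rate
    during the silent period of each repetition, averaged across repetitions.
    The SD is that of per-bin rates over the baseline interval, pooled across
    trials.
    """
    t0, t1 = block.baseline_interval
    sel = (block.times >= t0) & (block.times < t1)
    if not np.any(sel):
        raise ValueError("baseline interval covers no bins")
    rates = block.trials[:, sel] / block.bin_width
    return float(rates.max(axis=1).mean()), float(rates.std())


def detect_onset(
    rate: np.ndarray,
    baseline_rate: float,
    baseline_sd: float,
    k_sd: float = 4.0,
) -> int | None:
    """First bin above baseline + k_sd * SD that is followed by a second one.

    Returns the bin index, or None when no such pair exists (a valid result
    for unresponsive cells).
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    rate = np.asarray(rate, dtype=float)
    above = rate > baseline_rate + k_sd * baseline_sd
    pair = above[:-1] & above[1:]
    idx = np.flatnonzero(pair)
    return int(idx[0]) if idx.size else None


def detect_offset(
    rate: np.ndarray,
    baseline_rate: float,
    baseline_sd: float,
    k_sd: float = 4.0,
) -> int | None:
    """Latest bin above threshold with >= 2 of 3 consecutive bins above.

    Backward scan mirroring :func:`detect_onset`: starting from the most
    recent bin, the offset is the first (latest) above-threshold bin for which
    at least two of the three bins ending there exceed threshold.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    rate = np.asarray(rate, dtype=float)
    above = rate > baseline_rate + k_sd * baseline_sd
    for b in range(rate.size - 1, -1, -1):
        if not above[b]:
            continue
        window = above[max(0, b - 2) : b + 1]
        if window.sum() >= min(2, b + 1):
            return b
    return None


@dataclass
class SineFit:
    peak_rate: float  # Hz
    onset: float  # s
    duration: float  # s
    baseline: float  # Hz
    residual: float  # RMS Hz
    converged: bool


def fit_rectified_sine(
    rate: np.ndarray,
    bin_width: float,
    baseline: float = 0.0,
    init: tuple[float, float, float] | None = None,
) -> SineFit:
    """Bounded least-squares fit of the rectified-sine family to a PSTH.

    ``init`` is (peak, onset, duration); when omitted it is seeded from the
    4-SD onset/offset detectors (falling back to crude moments).  Onset and
    duration are continuous (not snapped to bins).
    """
    rate = np.asarray(rate, dtype=float)
    t = (np.arange(rate.size) + 0.5) * bin_width
    if not np.any(rate > baseline):
        raise ValueError("PSTH has no supra-baseline bins")
    if init is None:
        sd = float(rate[rate <= np.percentile(rate, 50)].std())
        on = detect_onset(rate, baseline, max(sd, 1e-9))
        off = detect_offset(rate, baseline, max(sd, 1e-9))
        if on is None or off is None or off <= on:
            on = int(np.argmax(rate > baseline))
            off = rate.size - 1 - int(np.argmax(rate[::-1] > baseline))
        peak0 = float(rate.max() - baseline)
        init = (peak0, on * bin_width, max((off - on + 1) * bin_width, bin_width))

    def resid(p: np.ndarray) -> np.ndarray:
        peak, onset, duration = p
        return rectified_sine_rate(t, peak, onset, duration, baseline) - rate

    lb = [0.0, -10.0 * t[-1], bin_width / 2.0]
    ub = [10.0 * float(rate.max() - baseline + 1.0), 10.0 * t[-1], 10.0 * t[-1]]
    p0 = np.clip(np.asarray(init, dtype=float), lb, ub)
    sol = least_squares(resid, p0, bounds=(lb, ub))
    return SineFit(
        peak_rate=float(sol.x[0]),
        onset=float(sol.x[1]),
        duration=float(sol.x[2]),
        baseline=baseline,
        residual=float(np.sqrt(np.mean(sol.fun**2))),
        converged=bool(sol.success),
    )


def rsi(region: RegionResponse) -> float:
    """Response symmetry index (Max - Opp) / (Max + Opp), in [-1, 1]."""
    total = region.max_response + region.opp_response
    if total <= 0:
        raise ValueError("RSI undefined when both region responses are zero")
    return (region.max_response - region.opp_response) / total


@dataclass
class TuningStats:
    dsi: float  # resultant length in [0, 1]
    preferred_direction: float  # deg; NaN when undefined (uniform responses)
    circular_variance: float  # 1 - resultant length
    angular_deviation: float  # deg, sqrt(2 CV)


def tuning_stats(responses: np.ndarray, directions: np.ndarray | None = None) -> TuningStats:
    """Resultant-vector direction-tuning statistics over sampled directions.

    DSI is the normalized vector-sum length; the preferred direction is the
    resultant angle (NaN-flagged when responses are direction-uniform);
    circular variance = 1 - DSI; angular deviation = sqrt(2 CV) in degrees.
    """
    responses = np.asarray(responses, dtype=float)
    if directions is None:
        directions = np.arange(responses.size) * (360.0 / responses.size)
    directions = np.asarray(directions, dtype=float)
    if np.any(responses < 0):
        raise ValueError("responses must be non-negative")
    total = responses.sum()
    if total <= 0:
        raise ValueError("tuning statistics undefined for all-zero responses")
    theta = np.deg2rad(directions)
    vec = np.array([np.sum(responses * np.cos(theta)), np.sum(responses * np.sin(theta))]) / total
    r = float(np.linalg.norm(vec))
    angle = float(np.rad2deg(np.arctan2(vec[1], vec[0]))) if r > 1e-12 else float("nan")
    cv = 1.0 - r
    return TuningStats(
        dsi=r,
        preferred_direction=angle,
        circular_variance=cv,
        angular_deviation=float(np.rad2deg(np.sqrt(2.0 * cv))),
    )


def quality_index(trials: np.ndarray | TrialBlock) -> float:
    """QI = Var_t[mean-over-trials response] / mean-over-trials[Var_t[trial]].

    1 for identical (non-constant) trials; ~1/N for independent noise.
    """
    if isinstance(trials, TrialBlock):
        trials = trials.trials
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] < 2:
        raise ValueError("quality index needs at least two trials")
    denom = trials.var(axis=1).mean()
    if denom == 0:
        raise ValueError("quality index undefined for all-constant trials")
    return float(trials.mean(axis=0).var() / denom)


def _exp_model(t: np.ndarray, p: np.ndarray, two_term: bool) -> np.ndarray:
    if two_term:
        a1, tau1, a2, tau2, c = p
        return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c
    a1, tau1, c = p
    return a1 * np.exp(-t / tau1) + c


def dff(
    trace: np.ndarray,
    intersweep_mask: np.ndarray,
    sample_dt: float = 1.0,
    two_term: bool = False,
    smooth_window: int = 4,
) -> np.ndarray:
    """Delta-F/F0 with an exponential-decay baseline fit to intersweep samples.

    The baseline F0(t) (photobleaching decay) is a one- or two-term
    exponential fit to the fluorescence during intersweep intervals, then
    evaluated over the whole trace; dF/F0 = (F - F0)/F0 is smoothed with a
    sliding average of ``smooth_window`` samples.  Raises when the fitted F0
    is not strictly positive everywhere.
    """
    trace = np.asarray(trace, dtype=float)
    intersweep_mask = np.asarray(intersweep_mask, dtype=bool)
    if trace.shape != intersweep_mask.shape:
        raise ValueError("trace and intersweep_mask shapes differ")
    if intersweep_mask.sum() < (5 if two_term else 3):
        raise ValueError("too few intersweep samples to fit the baseline")
    t = np.arange(trace.size) * sample_dt
    tb, fb = t[intersweep_mask], trace[intersweep_mask]
    span = max(float(fb.max() - fb.min()), 1e-12)
    tau0 = max(t[-1] / 3.0, sample_dt)
    if two_term:
        p0 = [span, tau0, span / 2.0, tau0 / 5.0, float(fb.min())]
        lb = [-np.inf, sample_dt / 10.0, -np.inf, sample_dt / 10.0, -np.inf]
        ub = [np.inf, np.inf, np.inf, np.inf, np.inf]
    else:
        p0 = [span, tau0, float(fb.min())]
        lb = [-np.inf, sample_dt / 10.0, -np.inf]
        ub = [np.inf, np.inf, np.inf]
    sol = least_squares(lambda p: _exp_model(tb, p, two_term) - fb, p0, bounds=(lb, ub))
    f0 = _exp_model(t, sol.x, two_term)
    if np.any(f0 <= 0):
        raise ValueError("fitted baseline F0 is not positive everywhere")
    out = (trace - f0) / f0
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        out = np.convolve(out, kernel, mode="same")
    return out
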