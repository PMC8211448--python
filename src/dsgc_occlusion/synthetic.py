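"""Ground-truth-known synthetic inputs for the metrics pipeline.

Generators for spike-count trial blocks (rectified-sine mean + sub-Poisson
count noise), direction-tuning blocks, and photobleaching fluorescence traces
with known transients.  Every artifact carries its :class:`GroundTruth`, so
round-trip tests can compare recovered parameters against what generated the
data.  Randomness is hierarchical: a master seed spawns per-trial substreams,
so adding trials never perturbs earlier draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .metrics import TrialBlock
from .responses import rectified_sine_rate, tuning_gain

__all__ = ["GroundTruth", "make_trial_block", "make_tuning_block", "make_fluorescence_trace"]


@dataclass
class GroundTruth:
    """Exact generator inputs (parameters, seed, noise settings) of a dataset."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None


def make_trial_block(
    peak_rate: float,
    onset: float,
    duration: float,
    n_trials: int = 6,
    bin_width: float = 0.025,
    t_total: float = 3.0,
    baseline_rate: float = 0.0,
    noise_var: float = 0.4,
    seed: int = 0,
) -> tuple[TrialBlock, GroundTruth]:
    """Spike-count trials from a rectified-sine mean rate with count noise.

    Counts per bin are Gaussian(mean rate x bin width, noise_var), clipped and
    integerized, on bins with evoked drive; baseline spikes are Poisson.  At
    bin means below ``noise_var`` (the rising/falling edges of the transient)
    the variance is capped at the mean — its Poisson ceiling — so the constant
    -variance contract applies to response bins while edge bins do not emit
    counts their mean rate cannot support.  The pre-onset segment is the
    designated baseline interval.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = np.random.SeedSequence(seed)
    times = (np.arange(int(round(t_total / bin_width))) + 0.5) * bin_width
    mean_rate = rectified_sine_rate(times, peak_rate, onset, duration, 0.0)
    mean_counts = np.asarray(mean_rate) * bin_width

    trials = np.zeros((n_trials, times.size))
    for i, s in enumerate(ss.spawn(n_trials)):
        rng = np.random.default_rng(s)
        evoked = mean_counts > 0
        row = np.zeros_like(mean_counts)
        if noise_var > 0:
            mu = mean_counts[evoked]
            draws = rng.normal(mu, np.sqrt(np.minimum(noise_var, mu)))
            row[evoked] = np.rint(np.clip(draws, 0.0, None))
        else:
            row[evoked] = np.rint(mean_counts[evoked])
        if baseline_rate > 0:
            row += rng.poisson(baseline_rate * bin_width, size=row.shape)
        trials[i] = row

    block = TrialBlock(
        trials=trials,
        bin_width=bin_width,
        baseline_interval=(0.0, max(onset, 0.0)),
        meta={"generator": "make_trial_block"},
    )
    truth = GroundTruth(
        kind="trial_block",
        params={
            "peak_rate": peak_rate,
            "onset": onset,
            "duration": duration,
            "baseline_rate": baseline_rate,
            "noise_var": noise_var,
            "bin_width": bin_width,
        },
        seed=seed,
    )
    return block, truth


def make_tuning_block(
    preferred_direction: float,
    tuning_width: float,
    peak_response: float,
    n_reps: int = 3,
    directions: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TrialBlock, GroundTruth]:
    """Per-direction spike-count responses over eight (default) directions.

    Response to direction d is peak x Gaussian tuning gain plus optional
    Gaussian noise, clipped non-negative.  Rows are repetitions, columns
    directions (stored in ``direction_labels``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if directions is None:
        directions = np.arange(8) * 45.0
    directions = np.asarray(directions, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gains = np.array([tuning_gain(preferred_direction, d, tuning_width) for d in directions])
    mean = peak_response * gains
    trials = np.clip(rng.normal(mean[None, :], noise_sd, size=(n_reps, directions.size)), 0.0, None)
    block = TrialBlock(
        trials=trials,
        bin_width=1.0,
        direction_labels=directions,
        meta={"generator": "make_tuning_block"},
    )
    truth = GroundTruth(
        kind="tuning_block",
        params={
            "preferred_direction": preferred_direction,
            "tuning_width": tuning_width,
            "peak_response": peak_response,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return block, truth


def make_fluorescence_trace(
    n_samples: int = 1200,
    sample_dt: float = 0.05,
    f0_amplitude: float = 100.0,
    bleach_tau: float = 30.0,
    f_offset: float = 50.0,
    transient_starts: tuple[float, ...] = (10.0, 30.0),
    transient_duration: float = 2.0,
    transient_amplitude: float = 0.5,
    intersweep_intervals: tuple[tuple[float, float], ...] = ((0.0, 8.0), (20.0, 28.0), (40.0, 48.0)),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Fluorescence trace: exponential bleaching + half-sine transients + noise.

    ``transient_amplitude`` is expressed as a fraction of the local baseline
    F0, so the ideal dF/F0 readout of a transient peak equals it.  Returns
    (trace, intersweep_mask, ground_truth).
    """
    if bleach_tau <= 0:
        raise ValueError("bleach_tau must be positive")
    t = np.arange(n_samples) * sample_dt
    f0 = f0_amplitude * np.exp(-t / bleach_tau) + f_offset
    trace = f0.copy()
    for start in transient_starts:
        sel = (t >= start) & (t < start + transient_duration)
        phase = (t[sel] - start) / transient_duration
        trace[sel] += transient_amplitude * f0[sel] * np.sin(np.pi * phase)
    mask = np.zeros(n_samples, dtype=bool)
    for lo, hi in intersweep_intervals:
        mask |= (t >= lo) & (t < hi)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        trace = trace + rng.normal(0.0, noise_sd, size=n_samples)
    truth = GroundTruth(
        kind="fluorescence_trace",
        params={
            "f0_amplitude": f0_amplitude,
            "bleach_tau": bleach_tau,
            "f_offset": f_offset,
            "transient_starts": list(transient_starts),
            "transient_duration": transient_duration,
            "transient_amplitude": transient_amplitude,
            "noise_sd": noise_sd,
            "sample_dt": sample_dt,
        },
        seed=seed,
    )
    return trace, mask, truth
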