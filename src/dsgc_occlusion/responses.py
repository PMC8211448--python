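"""Rectified-sine response model and per-cell parameter distributions.

A DSGC's trial-mean response to the moving edge is a half-rectified sine:
amplitude = peak firing rate, period = 2 x response duration, phase = onset.
Onset scatter follows four-parameter beta laws per condition; duration follows
a linear onset->duration relation with Gaussian scatter; direction tuning is a
Gaussian in wrapped angular difference whose width is the angular deviation
sqrt(2 x circular variance).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DurationLine, OnsetDistribution, ResponseConfig, SpeedScaling
from .geometry import CellMosaic, wrap_angle

__all__ = [
    "rectified_sine_rate",
    "sample_onset",
    "duration_from_onset",
    "scale_for_speed",
    "tuning_gain",
    "sample_tuning_widths",
    "sample_peak_rates",
    "PopulationParams",
    "draw_population_params",
]


def rectified_sine_rate(
    t: np.ndarray | float,
    peak_rate: float,
    t_on: float,
    duration: float,
    baseline_rate: float = 0.0,
) -> np.ndarray | float:
    """Firing rate (Hz) at time(s) ``t`` of the rectified-sine response.

    rate(t) = baseline + peak * max(0, sin(pi (t - t_on) / duration)) on
    [t_on, t_on + duration], baseline elsewhere.  Continuous and non-negative.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(t, dtype=float)
    phase = (t - t_on) / duration
    evoked = np.where((phase >= 0) & (phase <= 1), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    out = baseline_rate + peak_rate * evoked
    return float(out) if out.ndim == 0 else out


def sample_onset(dist: OnsetDistribution, n: int, seed: int | np.random.SeedSequence | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` onset times (s): lo + (hi - lo) * Beta(a, b)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return dist.lo + (dist.hi - dist.lo) * rng.beta(dist.shape_a, dist.shape_b, size=n)


def duration_from_onset(
    onset: np.ndarray | float,
    line: DurationLine,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> np.ndarray:
    """Duration (s) from the linear onset->duration relation, floored."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    onset = np.atleast_1d(np.asarray(onset, dtype=float))
    noise = rng.normal(0.0, line.noise_sd_s, size=onset.shape) if line.noise_sd_s > 0 else 0.0
    return np.maximum(line.floor_s, line.intercept_s + line.slope * onset + noise)


def scale_for_speed(
    onset: np.ndarray | float,
    duration: np.ndarray | float,
    speed: float,
    scaling: SpeedScaling,
) -> tuple[np.ndarray, np.ndarray]:
    """Adjust onset offsets and durations for a stimulus speed.

    At the reference speed (330 um/s) parameters are unchanged.  With
    ``time_rescale`` both quantities shrink as (ref/speed) — the response keeps
    a fixed spatial footprint; the additive onset line and the duration
    power law act on top of (or instead of) the rescaling.
    Speeds outside the calibrated 330-2640 um/s range extrapolate.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    ref = scaling.reference_speed_ums
    onset = np.asarray(onset, dtype=float)
    duration = np.asarray(duration, dtype=float)
    if scaling.time_rescale:
        onset = onset * (ref / speed)
    onset = onset + scaling.onset_slope_s_per_ums * (speed - ref)
    duration = duration * scaling.duration_coeff * (speed / ref) ** scaling.duration_exponent
    return onset, duration


def tuning_gain(
    preferred_direction: np.ndarray | float,
    motion_direction: float,
    tuning_width: np.ndarray | float,
) -> np.ndarray | float:
    """Normalized Gaussian direction-tuning gain in [0, 1].

    gain = exp(-delta^2 / (2 width^2)) with delta the wrapped angular
    difference (deg) and width the angular deviation (deg).
    """
    width = np.asarray(tuning_width, dtype=float)
    if np.any(width <= 0):
        raise ValueError("tuning_width must be positive")
    delta = wrap_angle(np.asarray(preferred_direction, dtype=float) - motion_direction)
    gain = np.exp(-(delta**2) / (2.0 * width**2))
    return float(gain) if np.ndim(gain) == 0 else gain


def sample_tuning_widths(
    n: int,
    cv_mean: float = 0.25,
    cv_sd: float = 0.08,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> np.ndarray:
    """Tuning widths (deg): angular deviation of Gaussian-sampled circular variance.

    Circular variances are N(cv_mean, cv_sd^2) truncated to (0, 1) by
    rejection; width = sqrt(2 CV) radians, returned in degrees.
    """
    if not 0 < cv_mean < 1:
        raise ValueError("cv_mean must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cv = rng.normal(cv_mean, cv_sd, size=n)
    if cv_sd > 0:
        bad = (cv <= 0) | (cv >= 1)
        while np.any(bad):
            cv[bad] = rng.normal(cv_mean, cv_sd, size=int(bad.sum()))
            bad = (cv <= 0) | (cv >= 1)
    return np.rad2deg(np.sqrt(2.0 * cv))


def sample_peak_rates(
    n: int,
    mean_hz: float,
    shape: float = 4.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> np.ndarray:
    """Gamma-distributed peak firing rates (Hz), positive by construction.

    Stand-in for sampling from recorded peak rates: gamma with the configured
    shape and mean (occlusion-null means are set below fullfield-preferred).
    """
    if mean_hz <= 0 or shape <= 0:
        raise ValueError("mean_hz and shape must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.gamma(shape, mean_hz / shape, size=n)


@dataclass
class PopulationParams:
    """Per-cell response parameters for one simulation block.

    Onset offsets are relative to the edge crossing each cell's position label
    (fullfield modes) or to the emergence instant (occlusion modes); all
    timing fields are already rescaled for the block's stimulus speed.
    """

    peak_fullfield: np.ndarray  # (n,) Hz, before tuning gain
    peak_occlusion_null: np.ndarray  # (n,) Hz
    tuning_width: np.ndarray  # (n,) deg
    onset_offset: np.ndarray  # (n,) s, fullfield, rel. to label crossing
    duration: np.ndarray  # (n,) s, fullfield
    null_latency: np.ndarray  # (n,) s, rel. to emergence
    occlusion_duration: np.ndarray  # (n,) s, occlusion transients
    baseline_rate: float
    speed: float


def draw_population_params(
    mosaic: CellMosaic,
    cfg: ResponseConfig,
    speed: float,
    seed: int | np.random.SeedSequence = 0,
    baseline_rate_hz: float | None = None,
) -> PopulationParams:
    """Draw one block's per-cell parameters and rescale them for ``speed``.

    Parameters are drawn once per block and shared by its repetitions; only
    the count noise differs across repetitions.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n = mosaic.n_cells

    peak_ff = sample_peak_rates(n, cfg.peak_mean_fullfield_hz, cfg.peak_shape, rng)
    peak_null = sample_peak_rates(n, cfg.peak_mean_occlusion_null_hz, cfg.peak_shape, rng)
    widths = sample_tuning_widths(n, cfg.tuning_cv_mean, cfg.tuning_cv_sd, rng)

    onset = sample_onset(cfg.onset_fullfield, n, rng)
    duration = duration_from_onset(onset, cfg.duration_fullfield, rng)
    latency = sample_onset(cfg.onset_occlusion_null, n, rng)
    occ_duration = duration_from_onset(latency, cfg.duration_occlusion, rng)

    onset, duration = scale_for_speed(onset, duration, speed, cfg.speed_scaling)
    latency, occ_duration = scale_for_speed(latency, occ_duration, speed, cfg.speed_scaling)
    latency = np.maximum(latency, 0.0)  # occlusion responses never precede emergence

    return PopulationParams(
        peak_fullfield=peak_ff,
        peak_occlusion_null=peak_null,
        tuning_width=widths,
        onset_offset=onset,
        duration=np.maximum(duration, cfg.duration_fullfield.floor_s),
        null_latency=latency,
        occlusion_duration=np.maximum(occ_duration, cfg.duration_occlusion.floor_s),
        baseline_rate=cfg.baseline_rate_hz if baseline_rate_hz is None else baseline_rate_hz,
        speed=speed,
    )
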