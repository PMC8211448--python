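"""Configuration for the DSGC population model.

Every tunable parameter of the simulation lives here, grouped per stage, with
the defaults the package documents in ``docs/methods.md``.  Configs round-trip
to flat YAML/JSON mappings so every run can log the fully resolved parameter
set alongside its seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "GeometryConfig",
    "OnsetDistribution",
    "DurationLine",
    "SpeedScaling",
    "ResponseConfig",
    "OccluderConfig",
    "StimulusConfig",
    "DecoderConfig",
    "CoincidenceConfig",
    "ExperimentConfig",
    "load_config",
]


@dataclass
class GeometryConfig:
    """Mosaic geometry of the two DSGC subtypes.

    Each subtype is an independent grid-with-jittered-spacings lattice whose
    successive horizontal/vertical nearest-neighbor distances are
    N(spacing_mean, spacing_sd^2) draws, centered on ``center_um`` so that the
    occluder sits approximately in the middle of the array.
    """

    n_cells: int = 1000
    spacing_mean_um: float = 39.0
    spacing_sd_um: float = 16.0
    aspect: float = 2.0  # columns:rows ratio of the lattice
    center_um: tuple[float, float] = (1800.0, 800.0)
    jitter_halfwidth_deg: float = 14.1
    rf_radius_mean_um: float = 88.0
    rf_radius_sd_um: float = 14.8
    rf_scale: float = 1.25
    displacement_fraction: float = 0.5


@dataclass
class OnsetDistribution:
    """Four-parameter beta law for spiking-response onset times (s).

    Draws are ``lo + (hi - lo) * Beta(shape_a, shape_b)``.  Fullfield onsets
    are measured relative to the moving edge crossing the cell's position
    label; occlusion-null onsets relative to the emergence instant.
    """

    lo: float
    hi: float
    shape_a: float
    shape_b: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("OnsetDistribution requires lo < hi")
        if self.shape_a <= 0 or self.shape_b <= 0:
            raise ValueError("beta shape parameters must be positive")

    @property
    def mean(self) -> float:
        a, b = self.shape_a, self.shape_b
        return self.lo + (self.hi - self.lo) * a / (a + b)


@dataclass
class DurationLine:
    """Linear onset->duration relation with Gaussian scatter and a floor."""

    intercept_s: float
    slope: float
    noise_sd_s: float
    floor_s: float = 0.05


@dataclass
class SpeedScaling:
    """How response timing changes with stimulus speed, relative to 330 um/s.

    With ``time_rescale`` (default) onset scatter, latencies and durations are
    multiplied by (330/speed): the response occupies a fixed spatial footprint.
    ``onset_slope_s_per_ums`` adds the alternative additive linear onset shift
    intercept+slope*(speed-330); ``duration_coeff*(speed/330)**duration_exponent``
    scales durations.
    """

    reference_speed_ums: float = 330.0
    time_rescale: bool = True
    onset_slope_s_per_ums: float = 0.0
    duration_coeff: float = 1.0
    duration_exponent: float = -1.0


@dataclass
class ResponseConfig:
    """Per-cell response-parameter distributions (rectified-sine model)."""

    onset_fullfield: OnsetDistribution = field(
        default_factory=lambda: OnsetDistribution(-0.30, 0.30, 3.0, 3.0)
    )
    onset_occlusion_null: OnsetDistribution = field(
        default_factory=lambda: OnsetDistribution(0.0, 0.15, 1.5, 2.5)
    )
    duration_fullfield: DurationLine = field(
        default_factory=lambda: DurationLine(0.90, -0.5, 0.10)
    )
    duration_occlusion: DurationLine = field(
        default_factory=lambda: DurationLine(0.25, -0.5, 0.04)
    )
    # gamma stand-ins for peak firing rates (shape, mean)
    peak_shape: float = 4.0
    peak_mean_fullfield_hz: float = 40.0
    peak_mean_occlusion_null_hz: float = 20.0
    # Gaussian over circular variance, truncated to (0, 1)
    tuning_cv_mean: float = 0.25
    tuning_cv_sd: float = 0.08
    baseline_rate_hz: float = 0.0
    speed_scaling: SpeedScaling = field(default_factory=SpeedScaling)


@dataclass
class OccluderConfig:
    center_um: tuple[float, float] = (1800.0, 800.0)
    diameter_um: float = 220.0


@dataclass
class StimulusConfig:
    speed_ums: float = 330.0
    direction_deg: float = 0.0
    dt_s: float = 0.010
    margin_um: float = 250.0  # bar starts/ends this far outside the lattice
    count_noise_var: float = 0.4
    # "band": occluder interrupts the edge for cells along the motion axis
    # (1D response logic); "disc": strict 2D footprint membership.
    occlusion_geometry: str = "band"


@dataclass
class DecoderConfig:
    noisy_labels: bool = True
    resample_labels_per_bin: bool = True
    emergence_window_s: float = 0.125
    um_per_degree: float = 31.0


@dataclass
class CoincidenceConfig:
    filter_halfwidth_s: float = 0.5
    monitor_radius_um: float = 220.0  # one occluder diameter around its center
    detection_window_s: float = 0.125
    n_thresholds: int = 200


@dataclass
class ExperimentConfig:
    """Master configuration: experiment sweeps plus all module parameters."""

    speeds_ums: tuple[float, ...] = (330.0, 660.0, 1320.0, 1980.0, 2640.0)
    baseline_rates_hz: tuple[float, ...] = (0.0, 0.025, 0.1)
    roc_baseline_rates_hz: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0, 50.0)
    n_blocks: int = 100
    n_reps: int = 10
    seed: int = 0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    response: ResponseConfig = field(default_factory=ResponseConfig)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    occluder: OccluderConfig = field(default_factory=OccluderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    coincidence: CoincidenceConfig = field(default_factory=CoincidenceConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=list))


def _build(cls: type, data: dict[str, Any]) -> Any:
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        nested = {
            "geometry": GeometryConfig,
            "response": ResponseConfig,
            "stimulus": StimulusConfig,
            "occluder": OccluderConfig,
            "decoder": DecoderConfig,
            "coincidence": CoincidenceConfig,
            "onset_fullfield": OnsetDistribution,
            "onset_occlusion_null": OnsetDistribution,
            "duration_fullfield": DurationLine,
            "duration_occlusion": DurationLine,
            "speed_scaling": SpeedScaling,
        }.get(f.name)
        if nested is not None and isinstance(value, dict):
            value = _build(nested, value)
        elif f.name.endswith(("_ums", "_hz", "_um")) and isinstance(value, list):
            value = tuple(value)
        elif f.name == "center_um" and isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML or JSON file.

    Missing keys fall back to package defaults, so a config file only needs to
    state what it overrides.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise TypeError(f"config root must be a mapping, got {type(data)!r}")
    return _build(ExperimentConfig, data)
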