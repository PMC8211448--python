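"""Two-dimensional mosaics of the two On-Off DSGC subtypes.

Each subtype (posterior-preferring cells aligned with the bar-motion axis,
anterior-preferring cells opposing it) is laid out as an independent lattice
whose successive horizontal and vertical nearest-neighbor distances are
Gaussian draws (mean 39 um, SD 16 um by default).  Preferred directions get
uniform jitter of +/-14.1 deg around the subtype axis; receptive-field widths
are scaled dendritic-field radii (N(88, 14.8^2) um x 1.25); decoder position
labels are the soma positions displaced toward the preferred side of the RF.

"Preferred side" is the side of the RF a preferred-direction stimulus enters
first, i.e. the direction opposite the preferred-direction vector.  The RF
(and hence the label) of a DSGC is displaced toward that side, which is what
lets an edge emerging from behind an occluder activate only the exposed
preferred-side region of nearby cells.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "WITH_MOTION",
    "AGAINST_MOTION",
    "CellMosaic",
    "generate_mosaic",
    "assign_preferred_directions",
    "sample_rf_widths",
    "assign_position_labels",
    "build_mosaic",
    "horizontal_spacings",
    "vertical_spacings",
]

WITH_MOTION = "pref_with_motion"
AGAINST_MOTION = "pref_against_motion"
_AXIS_DIRECTION = {WITH_MOTION: 0.0, AGAINST_MOTION: 180.0}


def wrap_angle(deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (degrees) to (-180, 180]."""
    wrapped = -(-(np.asarray(deg, dtype=float) - 180.0) % 360.0) + 180.0
    if np.isscalar(deg):
        return float(wrapped)
    return wrapped


@dataclass
class CellMosaic:
    """Positions, subtypes, tuning axes and decoder labels of a DSGC population.

    Arrays are aligned by cell index; ``preferred_direction``, ``rf_width`` and
    ``position_label`` stay ``None`` until the corresponding assignment step has
    run.  Row/column lattice indices are retained so neighbor spacings can be
    recomputed after generation.
    """

    subtype: np.ndarray  # (n,) str
    position: np.ndarray  # (n, 2) um
    row: np.ndarray  # (n,) lattice row index within subtype
    col: np.ndarray  # (n,) lattice column index within subtype
    preferred_direction: np.ndarray | None = None  # (n,) deg
    rf_width: np.ndarray | None = None  # (n,) um
    position_label: np.ndarray | None = None  # (n, 2) um
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.subtype)

    @property
    def cell_id(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def mask(self, subtype: str) -> np.ndarray:
        return self.subtype == subtype

    @property
    def axis_direction(self) -> np.ndarray:
        """Subtype axis direction (0 or 180 deg) per cell."""
        return np.where(self.mask(WITH_MOTION), 0.0, 180.0)

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_cells
        nan = np.full(n, np.nan)
        label = self.position_label if self.position_label is not None else np.full((n, 2), np.nan)
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "subtype": self.subtype,
                "x": self.position[:, 0],
                "y": self.position[:, 1],
                "row": self.row,
                "col": self.col,
                "pref_dir_deg": nan if self.preferred_direction is None else self.preferred_direction,
                "rf_width_um": nan if self.rf_width is None else self.rf_width,
                "label_x": label[:, 0],
                "label_y": label[:, 1],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the mosaic table plus a JSON sidecar of generator parameters."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.params, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CellMosaic":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        params = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        pref = df["pref_dir_deg"].to_numpy()
        rfw = df["rf_width_um"].to_numpy()
        label = df[["label_x", "label_y"]].to_numpy()
        return cls(
            subtype=df["subtype"].to_numpy(),
            position=df[["x", "y"]].to_numpy(),
            row=df["row"].to_numpy(),
            col=df["col"].to_numpy(),
            preferred_direction=None if np.all(np.isnan(pref)) else pref,
            rf_width=None if np.all(np.isnan(rfw)) else rfw,
            position_label=None if np.all(np.isnan(label)) else label,
            params=params,
        )


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, shape: tuple[int, ...]) -> np.ndarray:
    """N(mean, sd^2) draws with non-positive values re-drawn (rejection)."""
    draws = rng.normal(mean, sd, size=shape)
    if sd == 0:
        return draws
    bad = draws <= 0
    # mean/sd defaults put P(draw<=0) ~ 7e-3; a loop converges immediately
    while np.any(bad):
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = draws <= 0
    return draws


def _lattice_shape(n_cells: int, aspect: float) -> tuple[int, int]:
    cols = max(1, int(round(np.sqrt(n_cells * aspect))))
    rows = max(1, int(np.ceil(n_cells / cols)))
    return rows, cols


def generate_mosaic(
    n_cells: int = 1000,
    spacing_mean: float = 39.0,
    spacing_sd: float = 16.0,
    seed: int | np.random.SeedSequence = 0,
    aspect: float = 2.0,
    center: tuple[float, float] = (1800.0, 800.0),
) -> CellMosaic:
    """Generate both subtype mosaics with Gaussian nearest-neighbor spacings.

    Per subtype, a rows x cols lattice is built (cols:rows ~ ``aspect``) in
    which each row draws its own successive horizontal offsets and each column
    its own vertical offsets, all i.i.d. N(spacing_mean, spacing_sd^2) with
    non-positive draws rejected so ordering stays monotone.  The two subtypes
    use independent draws, so their positions are uncorrelated.  The joint
    array is centered on ``center``.
    """
    if spacing_mean <= 0:
        raise ValueError("spacing_mean must be positive")
    if spacing_sd < 0:
        raise ValueError("spacing_sd must be non-negative")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rows, cols = _lattice_shape(n_cells, aspect)

    subtypes, positions, row_idx, col_idx = [], [], [], []
    for subtype in (WITH_MOTION, AGAINST_MOTION):
        hx = _positive_normal(rng, spacing_mean, spacing_sd, (rows, cols - 1)) if cols > 1 else np.zeros((rows, 0))
        vy = _positive_normal(rng, spacing_mean, spacing_sd, (rows - 1, cols)) if rows > 1 else np.zeros((0, cols))
        x = np.concatenate([np.zeros((rows, 1)), np.cumsum(hx, axis=1)], axis=1)
        y = np.concatenate([np.zeros((1, cols)), np.cumsum(vy, axis=0)], axis=0)
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        keep = (rr * cols + cc).ravel() < n_cells
        pos = np.column_stack([x.ravel()[keep], y.ravel()[keep]])
        pos = pos - pos.mean(axis=0) + np.asarray(center, dtype=float)
        positions.append(pos)
        subtypes.append(np.full(n_cells, subtype, dtype=object))
        row_idx.append(rr.ravel()[keep])
        col_idx.append(cc.ravel()[keep])

    params = {
        "n_cells": n_cells,
        "spacing_mean": spacing_mean,
        "spacing_sd": spacing_sd,
        "aspect": aspect,
        "center": list(center),
        "rows": rows,
        "cols": cols,
        "seed": str(ss.entropy),
    }
    return CellMosaic(
        subtype=np.concatenate(subtypes),
        position=np.vstack(positions),
        row=np.concatenate(row_idx),
        col=np.concatenate(col_idx),
        params=params,
    )


def _spacings(mosaic: CellMosaic, subtype: str, axis: int) -> np.ndarray:
    m = mosaic.mask(subtype)
    pos = mosaic.position[m]
    rows, cols = mosaic.row[m], mosaic.col[m]
    out = []
    group, order = (rows, cols) if axis == 0 else (cols, rows)
    for g in np.unique(group):
        sel = group == g
        coords = pos[sel, axis][np.argsort(order[sel])]
        if len(coords) > 1:
            out.append(np.diff(coords))
    return np.concatenate(out) if out else np.empty(0)


def horizontal_spacings(mosaic: CellMosaic, subtype: str = WITH_MOTION) -> np.ndarray:
    """Successive horizontal nearest-neighbor distances within lattice rows."""
    return _spacings(mosaic, subtype, axis=0)


def vertical_spacings(mosaic: CellMosaic, subtype: str = WITH_MOTION) -> np.ndarray:
    """Successive vertical nearest-neighbor distances within lattice columns."""
    return _spacings(mosaic, subtype, axis=1)


def assign_preferred_directions(
    mosaic: CellMosaic,
    jitter_halfwidth: float = 14.1,
    seed: int | np.random.SeedSequence = 0,
) -> CellMosaic:
    """Jitter each cell's preferred direction uniformly around its subtype axis."""
    if not 0 <= jitter_halfwidth < 90:
        raise ValueError("jitter_halfwidth must be in [0, 90) degrees")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-jitter_halfwidth, jitter_halfwidth, size=mosaic.n_cells)
    pref = wrap_angle(mosaic.axis_direction + jitter)
    params = dict(mosaic.params, jitter_halfwidth=jitter_halfwidth)
    return replace(mosaic, preferred_direction=pref, params=params)


def sample_rf_widths(
    mosaic: CellMosaic,
    radius_mean: float = 88.0,
    radius_sd: float = 14.8,
    scale: float = 1.25,
    seed: int | np.random.SeedSequence = 0,
) -> CellMosaic:
    """RF widths = scale x N(radius_mean, radius_sd^2) dendritic radii, > 0."""
    if radius_mean <= 0:
        raise ValueError("radius_mean must be positive")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    radii = _positive_normal(rng, radius_mean, radius_sd, (mosaic.n_cells,))
    params = dict(mosaic.params, rf_radius_mean=radius_mean, rf_radius_sd=radius_sd, rf_scale=scale)
    return replace(mosaic, rf_width=scale * radii, params=params)


def assign_position_labels(mosaic: CellMosaic, displacement_fraction: float = 0.5) -> CellMosaic:
    """Displace decoder labels toward the preferred side of each RF.

    The preferred side lies opposite the preferred-direction vector (a
    preferred-direction stimulus enters the RF there first), so
    ``label = position - f * rf_width * unit(preferred_direction)``.
    """
    if not 0 <= displacement_fraction <= 1:
        raise ValueError("displacement_fraction must be in [0, 1]")
    if mosaic.rf_width is None:
        raise RuntimeError("rf_width must be assigned before position labels")
    if mosaic.preferred_direction is None:
        raise RuntimeError("preferred_direction must be assigned before position labels")
    theta = np.deg2rad(mosaic.preferred_direction)
    unit = np.column_stack([np.cos(theta), np.sin(theta)])
    label = mosaic.position - displacement_fraction * mosaic.rf_width[:, None] * unit
    params = dict(mosaic.params, displacement_fraction=displacement_fraction)
    return replace(mosaic, position_label=label, params=params)


def build_mosaic(cfg, seed: int | np.random.SeedSequence = 0) -> CellMosaic:
    """Run the full geometry pipeline from a :class:`GeometryConfig`."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pos, s_dir, s_rf = ss.spawn(3)
    mosaic = generate_mosaic(
        n_cells=cfg.n_cells,
        spacing_mean=cfg.spacing_mean_um,
        spacing_sd=cfg.spacing_sd_um,
        seed=s_pos,
        aspect=cfg.aspect,
        center=cfg.center_um,
    )
    mosaic = assign_preferred_directions(mosaic, cfg.jitter_halfwidth_deg, seed=s_dir)
    mosaic = sample_rf_widths(mosaic, cfg.rf_radius_mean_um, cfg.rf_radius_sd_um, cfg.rf_scale, seed=s_rf)
    return assign_position_labels(mosaic, cfg.displacement_fraction)
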