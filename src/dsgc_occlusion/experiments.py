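"""Paper-level experiments: paired decoding sweeps and the ROC ladder.

`run_decoding_experiment` runs paired full-field/occluded simulation blocks
across stimulus speeds and baseline rates and summarizes the decoded-position
and direction errors inside the 125 ms emergence window.  `run_roc_experiment`
runs the coincidence detector over a ladder of baseline firing rates and
reports ROC/AUC/accuracy per level.  Both write tidy CSVs plus the resolved
config when given an output directory.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coincidence import (
    RocResult,
    detector_score,
    fit_dog_filter,
    monitored_cells,
    roc_sweep,
    summed_monitor_rate,
)
from .config import ExperimentConfig
from .decoding import decode_run, emergence_window
from .geometry import CellMosaic, build_mosaic
from .responses import PopulationParams, draw_population_params
from .stimulus import Occluder, make_stimulus, run_block, simulate_trial

__all__ = [
    "paired_window_errors",
    "run_decoding_experiment",
    "run_roc_experiment",
]


def _subset_mosaic(mosaic: CellMosaic, mask: np.ndarray) -> CellMosaic:
    return CellMosaic(
        subtype=mosaic.subtype[mask],
        position=mosaic.position[mask],
        row=mosaic.row[mask],
        col=mosaic.col[mask],
        preferred_direction=mosaic.preferred_direction[mask],
        rf_width=mosaic.rf_width[mask],
        position_label=mosaic.position_label[mask],
        params=dict(mosaic.params, subset=int(mask.sum())),
    )


def _subset_params(params: PopulationParams, mask: np.ndarray) -> PopulationParams:
    return PopulationParams(
        peak_fullfield=params.peak_fullfield[mask],
        peak_occlusion_null=params.peak_occlusion_null[mask],
        tuning_width=params.tuning_width[mask],
        onset_offset=params.onset_offset[mask],
        duration=params.duration[mask],
        null_latency=params.null_latency[mask],
        occlusion_duration=params.occlusion_duration[mask],
        baseline_rate=params.baseline_rate,
        speed=params.speed,
    )


def paired_window_errors(
    cfg: ExperimentConfig,
    speed: float,
    baseline_rate: float,
    n_blocks: int,
    n_reps: int,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, float]:
    """Pooled emergence-window decoding errors for paired ff/occluded blocks.

    Each block draws a fresh mosaic and parameter set shared by both
    conditions; squared decoding errors are pooled over every trial and every
    time bin inside the 125 ms window after the edge clears the occluder.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_win = max(1, int(round(cfg.decoder.emergence_window_s / cfg.stimulus.dt_s)))
    errs: dict[tuple[str, str], list[np.ndarray]] = {
        (cond, mode): [] for cond in ("fullfield", "occluded") for mode in ("position", "direction")
    }
    for block_id, block_seed in enumerate(ss.spawn(n_blocks)):
        s_block, s_decode = block_seed.spawn(2)
        block = run_block(cfg, speed, baseline_rate, s_block, n_reps=n_reps, block_id=block_id)
        t_em = block["occluded"][0].emergence_time
        window = emergence_window(t_em, cfg.decoder.emergence_window_s)
        dstreams = iter(s_decode.spawn(4))
        for cond in ("fullfield", "occluded"):
            for mode in ("position", "direction"):
                trace = decode_run(
                    block[cond], block["mosaic"], block["params"], mode, cfg.decoder, next(dstreams)
                )
                centers = trace.times + cfg.stimulus.dt_s / 2.0
                insel = np.flatnonzero((centers >= window[0]) & (centers < window[1]))[:n_win]
                err = trace.estimates[:, insel] - trace.truth[None, insel]
                if mode == "direction":
                    err = (err + 180.0) % 360.0 - 180.0
                errs[(cond, mode)].append(err)

    def rmse(cond: str, mode: str) -> float:
        # pool trials of all blocks per window bin, then time-average RMSE(t)
        stacked = np.vstack(errs[(cond, mode)])
        with np.errstate(invalid="ignore"):
            per_bin = np.sqrt(np.nanmean(stacked**2, axis=0))
        per_bin = per_bin[~np.isnan(per_bin)]
        return float(per_bin.mean()) if per_bin.size else float("nan")

    ff_pos, occ_pos = rmse("fullfield", "position"), rmse("occluded", "position")
    ff_dir, occ_dir = rmse("fullfield", "direction"), rmse("occluded", "direction")
    return {
        "speed_um_s": speed,
        "baseline_hz": baseline_rate,
        "rmse_ff_um": ff_pos,
        "rmse_occ_um": occ_pos,
        "pct_position_decrease": 100.0 * (ff_pos - occ_pos) / ff_pos,
        "abs_decrease_um": ff_pos - occ_pos,
        "abs_decrease_deg": (ff_pos - occ_pos) / cfg.decoder.um_per_degree,
        "rmse_dir_ff_deg": ff_dir,
        "rmse_dir_occ_deg": occ_dir,
        "pct_direction_change": 100.0 * (ff_dir - occ_dir) / ff_dir,
    }


def run_decoding_experiment(
    cfg: ExperimentConfig,
    out_dir: str | Path | None = None,
    speeds: Sequence[float] | None = None,
    baseline_rates: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Sweep speeds x baseline rates; one summary row per combination."""
    speeds = list(speeds if speeds is not None else cfg.speeds_ums)
    baselines = list(baseline_rates if baseline_rates is not None else cfg.baseline_rates_hz)
    ss = np.random.SeedSequence(cfg.seed)
    rows = []
    for (speed, baseline), s in zip(
        [(v, b) for v in speeds for b in baselines], ss.spawn(len(speeds) * len(baselines))
    ):
        rows.append(paired_window_errors(cfg, speed, baseline, cfg.n_blocks, cfg.n_reps, s))
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "decoding_summary.csv", index=False)
        cfg.to_json(out / "resolved_config.json")
    return df


def _detection_mask(times: np.ndarray, dt: float, t_em: float, width: float) -> np.ndarray:
    # the detection window is centered on the occlusion event: the matched
    # filter encodes the response latency, so its output peaks at emergence
    centers = times + dt / 2.0
    return (centers >= t_em - width / 2.0) & (centers < t_em + width / 2.0)


def run_roc_experiment(
    cfg: ExperimentConfig,
    out_dir: str | Path | None = None,
    baseline_rates: Sequence[float] | None = None,
    n_trials_per_condition: int = 100,
) -> list[RocResult]:
    """Coincidence-detector ROC per baseline-firing level.

    Only the monitored subpopulation (against-motion cells within one occluder
    diameter of its center) is simulated: it alone feeds the detector.  The
    DoG filter is fit to the trial-averaged occlusion response of the first
    block at each level, then applied to every trial.
    """
    baselines = list(baseline_rates if baseline_rates is not None else cfg.roc_baseline_rates_hz)
    ss = np.random.SeedSequence(cfg.seed)
    n_reps = cfg.n_reps
    n_blocks = max(1, int(np.ceil(n_trials_per_condition / n_reps)))
    results: list[RocResult] = []

    for baseline, s_level in zip(baselines, ss.spawn(len(baselines))):
        occ_scores, ff_scores, occ_wins, ff_wins = [], [], [], []
        templates = []
        blocks = []
        for block_id, s_block in enumerate(s_level.spawn(n_blocks)):
            s_mosaic, s_params, s_noise = s_block.spawn(3)
            mosaic = build_mosaic(cfg.geometry, s_mosaic)
            params = draw_population_params(
                mosaic, cfg.response, cfg.stimulus.speed_ums, s_params, baseline_rate_hz=baseline
            )
            occluder = Occluder(center=cfg.occluder.center_um, diameter=cfg.occluder.diameter_um)
            subset = monitored_cells(mosaic, occluder, cfg.coincidence.monitor_radius_um)
            sub_mosaic = _subset_mosaic(mosaic, subset)
            sub_params = _subset_params(params, subset)
            stimulus = make_stimulus(mosaic, cfg.stimulus.speed_ums, margin=cfg.stimulus.margin_um)
            t_em = float(stimulus.arrival_time(occluder.x_exit))
            streams = iter(s_noise.spawn(2 * n_reps))
            block_rates = []
            for cond in ("occluded", "fullfield"):
                for rep in range(n_reps):
                    act = simulate_trial(
                        sub_mosaic,
                        sub_params,
                        stimulus,
                        occluder=occluder if cond == "occluded" else None,
                        noise_var=cfg.stimulus.count_noise_var,
                        dt=cfg.stimulus.dt_s,
                        seed=next(streams),
                        occlusion_geometry=cfg.stimulus.occlusion_geometry,
                        block_id=block_id,
                        trial_id=rep,
                    )
                    rate = summed_monitor_rate(act, np.ones(sub_mosaic.n_cells, dtype=bool))
                    mask = _detection_mask(act.times, cfg.stimulus.dt_s, t_em, cfg.coincidence.detection_window_s)
                    blocks.append((cond, rate, mask, act.times))
                    if cond == "occluded":
                        block_rates.append(rate)
            templates.append((np.mean(block_rates, axis=0), t_em, stimulus))

        template_rate, t_em0, stim0 = templates[0]
        times0 = np.arange(stim0.t_start, stim0.t_end, cfg.stimulus.dt_s)
        near = np.abs(times0 + cfg.stimulus.dt_s / 2.0 - t_em0) <= cfg.coincidence.filter_halfwidth_s
        template = template_rate[near] - np.median(template_rate)
        filt = fit_dog_filter(
            template,
            cfg.stimulus.dt_s,
            t=times0[near] - t_em0,
            halfwidth=cfg.coincidence.filter_halfwidth_s,
        )

        for cond, rate, mask, _times in blocks:
            score = detector_score(rate, filt, cfg.stimulus.dt_s)
            if cond == "occluded":
                occ_scores.append(score)
                occ_wins.append(mask)
            else:
                ff_scores.append(score)
                ff_wins.append(mask)

        result = roc_sweep(
            occ_scores[:n_trials_per_condition],
            ff_scores[:n_trials_per_condition],
            occ_wins[:n_trials_per_condition],
            ff_wins[:n_trials_per_condition],
            n_thresholds=cfg.coincidence.n_thresholds,
            baseline_hz=baseline,
        )
        results.append(result)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([r.summary() for r in results]).to_csv(out / "roc_summary.csv", index=False)
        for r in results:
            r.to_csv(out / f"roc_baseline_{r.baseline_hz:g}.csv")
        cfg.to_json(out / "resolved_config.json")
    return results
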