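"""End-to-end orchestration: simulate -> fit -> indices -> correlate/classify.

Stages communicate through the CSV artifacts defined in :mod:`.io`; each
stage checks its upstream artifact and raises a clear error naming the
stage to run first.  All randomness flows from the config seed, so a
rerun with an identical config reproduces every deterministic artifact
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation as corr_mod
from . import io as io_mod
from .classify import run_question
from .indices import assemble_index_series, compute_hrv_index_block, eda_indices
from .point_process import IGModelConfig, fit_amp_local, fit_ig_local
from .synthetic import SyntheticSessionSpec, simulate_study

DEFAULT_CONFIG = {
    "seed": 0,
    "n_subjects": 9,
    "effect_scale": 1.0,
    "session": {},              # overrides for SyntheticSessionSpec fields
    "delta": 1.0,               # index grid step for pipeline runs, s
    "rr": {"p": 1, "W_fit": 60.0},
    "eda": {"p": 1, "W_fit": 300.0, "q": 1},
    "question": 1,
    "w_grid": [20],
    "h_grid": [120],
    "metrics": ["median"],
    "t_grid": [20],
    "n_boot": 1000,
}


def merge_config(overrides: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}; run the '{stage}' stage first")
    return path


def stage_simulate(cfg: dict, outdir: Path) -> list:
    extra = {k: (tuple(v) if isinstance(v, list) else v)
             for k, v in cfg.get("session", {}).items()}
    spec = SyntheticSessionSpec(
        n_subjects=int(cfg["n_subjects"]),
        effect_scale=float(cfg["effect_scale"]),
        seed=int(cfg["seed"]), **extra)
    sessions = simulate_study(spec)
    io_mod.write_csv(io_mod.events_frame(sessions), outdir / "events.csv",
                     cfg, cfg["seed"])
    io_mod.write_csv(io_mod.tonic_frame(sessions), outdir / "tonic.csv",
                     cfg, cfg["seed"])
    io_mod.write_csv(io_mod.annotations_frame(sessions),
                     outdir / "annotations.csv", cfg, cfg["seed"])
    io_mod.write_csv(io_mod.truth_frame(sessions), outdir / "truth.csv",
                     cfg, cfg["seed"])
    return sessions


def fit_session_indices(r_peaks: np.ndarray, pulse_times: np.ndarray,
                        pulse_amps: np.ndarray, tonic_times: np.ndarray,
                        tonic_values: np.ndarray, cfg: dict):
    """Fit both point-process models and assemble the 15-index series."""
    delta = float(cfg["delta"])
    rr_cfg = IGModelConfig(p=int(cfg["rr"]["p"]),
                           W_fit=float(cfg["rr"]["W_fit"]), delta=delta)
    rr_traj = fit_ig_local(r_peaks, rr_cfg)
    hrv_vals, hrv_valid, hrv_grid = compute_hrv_index_block(rr_traj, r_peaks)

    eda_cfg = IGModelConfig(p=int(cfg["eda"]["p"]),
                            W_fit=float(cfg["eda"]["W_fit"]), delta=delta)
    eda_traj = fit_ig_local(pulse_times, eda_cfg)
    amp_traj = fit_amp_local(pulse_times, pulse_amps,
                             q=int(cfg["eda"]["q"]),
                             W_fit=float(cfg["eda"]["W_fit"]),
                             update_times=eda_traj.update_times)
    eda_vals, eda_valid = eda_indices(eda_traj, amp_traj, pulse_times,
                                      pulse_amps, tonic_times, tonic_values)
    idx = assemble_index_series(hrv_vals, hrv_valid, hrv_grid,
                                eda_vals, eda_valid, eda_traj.update_times)
    return idx, rr_traj, eda_traj, amp_traj


def stage_fit_indices(cfg: dict, outdir: Path) -> dict:
    events = io_mod.read_csv(_require(outdir / "events.csv", "simulate"))
    tonic = io_mod.read_csv(_require(outdir / "tonic.csv", "simulate"))
    traj_parts, idx_parts = [], []
    index_by_subject = {}
    for sid, g in events.groupby("subject_id"):
        rr = g.loc[g.channel == "rr", "time_s"].to_numpy(float)
        ep = g.loc[g.channel == "eda"].sort_values("time_s")
        tg = tonic[tonic.subject_id == sid]
        idx, rr_traj, *_ = fit_session_indices(
            rr, ep["time_s"].to_numpy(float),
            ep["amplitude_uS"].to_numpy(float),
            tg["time_s"].to_numpy(float), tg["tonic_uS"].to_numpy(float),
            cfg)
        index_by_subject[sid] = idx
        traj_parts.append(io_mod.trajectory_frame(sid, rr_traj))
        idx_parts.append(io_mod.index_frame(sid, idx))
    io_mod.write_csv(pd.concat(traj_parts, ignore_index=True),
                     outdir / "trajectories.csv", cfg, cfg["seed"])
    io_mod.write_csv(pd.concat(idx_parts, ignore_index=True),
                     outdir / "indices.csv", cfg, cfg["seed"])
    return index_by_subject


def stage_correlate(cfg: dict, outdir: Path) -> pd.DataFrame:
    idx_df = io_mod.read_csv(_require(outdir / "indices.csv", "indices"))
    by_subject = io_mod.index_series_from_frame(idx_df)
    parts = []
    for sid, idx in by_subject.items():
        parts.append(io_mod.correlation_frame(
            sid, corr_mod.rate_amp_correlations(idx)))
    out = pd.concat(parts, ignore_index=True)
    io_mod.write_csv(out, outdir / "correlation.csv", cfg, cfg["seed"])
    return out


def stage_classify(cfg: dict, outdir: Path):
    idx_df = io_mod.read_csv(_require(outdir / "indices.csv", "indices"))
    ann_df = io_mod.read_csv(_require(outdir / "annotations.csv", "simulate"))
    index_by_subject = io_mod.index_series_from_frame(idx_df)
    ann_by_subject = io_mod.annotations_from_frame(ann_df)
    result = run_question(
        index_by_subject, ann_by_subject, int(cfg["question"]),
        w_grid=tuple(cfg["w_grid"]), h_grid=tuple(cfg["h_grid"]),
        metrics=tuple(cfg["metrics"]), t_grid=tuple(cfg["t_grid"]),
        seed=int(cfg["seed"]), n_boot=int(cfg["n_boot"]))
    io_mod.write_csv(io_mod.predictions_frame(result.reports),
                     outdir / "predictions.csv", cfg, cfg["seed"])
    (outdir / "report.txt").write_text(io_mod.report_text(result))
    io_mod.write_csv(result.grid_table, outdir / "grid_table.csv",
                     cfg, cfg["seed"])
    return result


def run_pipeline(config: dict | None, outdir, stages=("all",)):
    """Run the requested stages in dependency order."""
    cfg = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    todo = set(stages)
    if "all" in todo:
        todo = {"simulate", "fit", "indices", "correlate", "classify"}
    results = {}
    if "simulate" in todo:
        results["sessions"] = stage_simulate(cfg, outdir)
    if "fit" in todo or "indices" in todo:
        results["indices"] = stage_fit_indices(cfg, outdir)
    if "correlate" in todo:
        results["correlation"] = stage_correlate(cfg, outdir)
    if "classify" in todo:
        results["question"] = stage_classify(cfg, outdir)
    return results
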