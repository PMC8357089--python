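"""CSV serialization of pipeline artifacts.

All artifacts are plain CSV with a single provenance comment line
(``# autonomics config=<hash> seed=<seed>``) so a rerun with the same
configuration is verifiably identical.  Schemas:

- events:      subject_id,channel,time_s,amplitude_uS  (amplitude empty for RR)
- tonic:       subject_id,time_s,tonic_uS
- annotations: subject_id,loc_s,roc_s,stage_idx,stage_start_s,stage_target
- truth:       subject_id,time_s,<ground-truth parameter columns>
- trajectory:  subject_id,update_time_s,param_name,value,converged
- indices:     subject_id,time_s,index_name,value,valid
- correlation: subject_id,time_s,pair,r,n_eff
- predictions: subject_id,window_start_s,label,probability,model
- waveform:    time_s,value
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, config: dict | None = None,
              seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# autonomics config={config_hash(config)} "
                     f"seed={seed}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def events_frame(sessions) -> pd.DataFrame:
    rows = []
    for s in sessions:
        rows.append(pd.DataFrame({
            "subject_id": s.subject_id, "channel": "rr",
            "time_s": s.r_peaks, "amplitude_uS": np.nan}))
        rows.append(pd.DataFrame({
            "subject_id": s.subject_id, "channel": "eda",
            "time_s": s.eda_pulse_times, "amplitude_uS": s.eda_pulse_amps}))
    return pd.concat(rows, ignore_index=True)


def tonic_frame(sessions) -> pd.DataFrame:
    return pd.concat([
        pd.DataFrame({"subject_id": s.subject_id, "time_s": s.tonic_times,
                      "tonic_uS": s.tonic_values})
        for s in sessions], ignore_index=True)


def annotations_frame(sessions) -> pd.DataFrame:
    rows = []
    for s in sessions:
        a = s.annotations
        for i, (st, tg) in enumerate(zip(a.stage_starts, a.stage_targets)):
            rows.append({"subject_id": s.subject_id, "loc_s": a.loc_s,
                         "roc_s": a.roc_s, "stage_idx": i,
                         "stage_start_s": st, "stage_target": tg,
                         "duration_s": a.duration})
    return pd.DataFrame(rows)


def annotations_from_frame(df: pd.DataFrame) -> dict:
    """Rebuild {subject_id: SessionAnnotations} from the annotations CSV."""
    from .synthetic import SessionAnnotations
    out = {}
    for sid, g in df.groupby("subject_id"):
        g = g.sort_values("stage_idx")
        starts = tuple(g["stage_start_s"].to_numpy(float))
        dur = float(g["duration_s"].iloc[0])
        out[sid] = SessionAnnotations(
            loc_s=float(g["loc_s"].iloc[0]), roc_s=float(g["roc_s"].iloc[0]),
            baseline_pre=(starts[0], starts[1]),
            baseline_post=(starts[-1], dur),
            stage_starts=starts,
            stage_targets=tuple(g["stage_target"].to_numpy(float)),
            duration=dur)
    return out


def truth_frame(sessions) -> pd.DataFrame:
    parts = []
    for s in sessions:
        df = s.truth.copy()
        df.insert(0, "subject_id", s.subject_id)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def trajectory_frame(subject_id: str, traj) -> pd.DataFrame:
    names = ["theta0"] + [f"theta{i+1}" for i in range(traj.theta.shape[1])] \
        + ["lambda"]
    cols = [traj.theta0] + [traj.theta[:, i]
                            for i in range(traj.theta.shape[1])] \
        + [traj.lambda_shape]
    parts = []
    for name, col in zip(names, cols):
        parts.append(pd.DataFrame({
            "subject_id": subject_id, "update_time_s": traj.update_times,
            "param_name": name, "value": col, "converged": traj.converged}))
    return pd.concat(parts, ignore_index=True)


def index_frame(subject_id: str, idx) -> pd.DataFrame:
    parts = []
    for ch in idx.values.columns:
        parts.append(pd.DataFrame({
            "subject_id": subject_id, "time_s": idx.grid,
            "index_name": ch, "value": idx.values[ch].to_numpy(),
            "valid": idx.valid[ch].to_numpy()}))
    return pd.concat(parts, ignore_index=True)


def index_series_from_frame(df: pd.DataFrame) -> dict:
    """Rebuild {subject_id: IndexSeries} from the indices CSV."""
    from .indices import ALL_CHANNELS, IndexSeries
    out = {}
    for sid, g in df.groupby("subject_id"):
        piv_v = g.pivot(index="time_s", columns="index_name", values="value")
        piv_m = g.pivot(index="time_s", columns="index_name", values="valid")
        grid = piv_v.index.to_numpy(float)
        out[sid] = IndexSeries(
            grid=grid,
            values=piv_v[list(ALL_CHANNELS)].reset_index(drop=True),
            valid=piv_m[list(ALL_CHANNELS)].astype(bool)
            .reset_index(drop=True))
    return out


def correlation_frame(subject_id: str, corrs: dict) -> pd.DataFrame:
    parts = []
    for pair, cs in corrs.items():
        parts.append(pd.DataFrame({
            "subject_id": subject_id, "time_s": cs.times, "pair": pair,
            "r": cs.r, "n_eff": cs.n_eff}))
    return pd.concat(parts, ignore_index=True)


def predictions_frame(reports: dict) -> pd.DataFrame:
    parts = []
    for model, rep in reports.items():
        df = rep.predictions.copy()
        df["model"] = model
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def report_text(result) -> str:
    """Machine-readable key-value report for one question's results."""
    lines = [f"question: {result.question}"]
    for k, v in result.best_config.items():
        lines.append(f"best_{k}: {v}")
    for modality, rep in result.reports.items():
        lines.append(f"auc_{modality}: {rep.pooled_auc:.4f}")
    for modality, (pt, lo, hi, sig) in result.auc_diff_cis.items():
        lines.append(f"auc_diff_multimodal_minus_{modality}: {pt:.4f}")
        lines.append(f"auc_diff_ci95_{modality}: [{lo:.4f}, {hi:.4f}]")
        lines.append(f"auc_diff_significant_{modality}: {sig}")
    surv = result.reports["multimodal"].surviving_features
    for held, feats in surv.items():
        names = ",".join(n for n, _ in feats)
        lines.append(f"surviving_features_heldout_{held}: {names}")
    return "\n".join(lines) + "\n"
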