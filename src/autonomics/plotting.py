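"""Figure-style outputs: prediction traces and EDA rate/amplitude panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def plot_predictions(predictions: pd.DataFrame,
                     ann_by_subject: dict, outdir,
                     model: str = "multimodal") -> list[Path]:
    """One panel per subject: held-out probability trace vs behavior."""
    if predictions.empty:
        raise ValueError("empty predictions artifact")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sub = predictions[predictions["model"] == model]
    paths = []
    for sid, g in sub.groupby("subject_id"):
        fig, ax = plt.subplots(figsize=(8, 2.5))
        t = g["window_start_s"].to_numpy(float) / 60.0
        ax.plot(t, g["probability"], color="tab:blue", lw=1,
                label="autonomic prediction")
        ax.plot(t, g["label"], "m*", ms=3, label="behavioral state")
        ann = ann_by_subject.get(sid)
        if ann is not None:
            for x, name in ((ann.loc_s, "LOC"), (ann.roc_s, "ROC")):
                ax.axvline(x / 60.0, color="k", ls=":", lw=0.8)
                ax.text(x / 60.0, 1.02, name, ha="center", fontsize=7)
        ax.set_ylim(-0.05, 1.1)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("P(state = 1)")
        ax.set_title(f"{sid}", fontsize=9)
        ax.legend(fontsize=6, loc="center right")
        path = outdir / f"prediction_{sid}.png"
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths


def plot_eda_panels(index_df: pd.DataFrame,
                    correlation_df: pd.DataFrame | None,
                    outdir) -> list[Path]:
    """Six stacked panels per subject: muPR, mu_amp, their correlation,
    sigmaPR, sigma_amp, and the SD-pair correlation."""
    if index_df.empty:
        raise ValueError("empty index artifact")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = [("muPR", "index"), ("mu_amp", "index"), ("mean", "corr"),
              ("sigmaPR", "index"), ("sigma_amp", "index"), ("sd", "corr")]
    paths = []
    for sid, g in index_df.groupby("subject_id"):
        fig, axes = plt.subplots(6, 1, figsize=(8, 9), sharex=True)
        for ax, (name, kind) in zip(axes, layout):
            if kind == "index":
                ch = g[g["index_name"] == name]
                v = ch["value"].to_numpy(float).copy()
                v[~ch["valid"].astype(bool).to_numpy()] = np.nan
                ax.plot(ch["time_s"].to_numpy(float) / 60.0, v, lw=0.8)
                ax.set_ylabel(name, fontsize=7)
            else:
                if correlation_df is None or correlation_df.empty:
                    ax.text(0.5, 0.5, "correlation artifact missing",
                            ha="center", va="center", fontsize=8,
                            transform=ax.transAxes)
                    ax.set_ylabel(f"r ({name})", fontsize=7)
                    continue
                cc = correlation_df[(correlation_df["subject_id"] == sid)
                                    & (correlation_df["pair"] == name)]
                ax.plot(cc["time_s"].to_numpy(float) / 60.0,
                        cc["r"].to_numpy(float), lw=0.8, color="tab:red")
                ax.axhline(0, color="k", lw=0.5)
                ax.set_ylim(-1.05, 1.05)
                ax.set_ylabel(f"r ({name})", fontsize=7)
        axes[-1].set_xlabel("time (min)")
        fig.suptitle(f"EDA rate vs amplitude — {sid}", fontsize=10)
        path = outdir / f"eda_panels_{sid}.png"
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
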