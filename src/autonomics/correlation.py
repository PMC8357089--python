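"""Sliding correlation between EDA pulse-rate and pulse-amplitude indices.

Quantifies, on the timescale of minutes, when the temporal (pulse rate)
and amplitude channels of phasic electrodermal activity carry correlated
versus complementary information.  Three stages:

1. median of each index within non-overlapping 20 s windows;
2. moving-average smoothing over 3-minute sliding windows (centered);
3. Pearson correlation over 10-minute sliding windows (trailing), one
   value per 20 s step.

Applied to the (muPR, mu_amp) and (sigmaPR, sigma_amp) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CorrelationSeries:
    """Per-window Pearson r; NaN where the window is incomplete/constant."""

    times: np.ndarray
    r: np.ndarray
    n_eff: np.ndarray


def _bin_median(values: np.ndarray, grid: np.ndarray, width: float):
    """Median within non-overlapping bins of ``width`` seconds."""
    t0 = grid[0]
    bins = ((grid - t0) // width).astype(int)
    nb = int(bins[-1]) + 1
    out = np.full(nb, np.nan)
    df = pd.Series(values).groupby(bins).median()
    out[df.index.to_numpy()] = df.to_numpy()
    centers = t0 + (np.arange(nb) + 0.5) * width
    return centers, out


def sliding_rate_amp_correlation(a: np.ndarray, b: np.ndarray,
                                 grid: np.ndarray,
                                 median_w: float = 20.0,
                                 smooth_w: float = 180.0,
                                 corr_w: float = 600.0) -> CorrelationSeries:
    """Three-stage sliding Pearson correlation between two index channels.

    ``a`` and ``b`` are index values on the common uniform ``grid``
    (NaN where masked).  Stage windows must nest:
    corr_w >= smooth_w >= median_w.  Correlations are emitted at each
    stage-1 step; windows that are incomplete (any NaN) or in which
    either smoothed series is constant come out NaN.

    Raises when the series is shorter than one correlation window.
    """
    if not (corr_w >= smooth_w >= median_w > 0):
        raise ValueError("window lengths must satisfy corr_w >= smooth_w "
                         ">= median_w > 0")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(a) != len(grid) or len(b) != len(grid):
        raise ValueError("series and grid lengths differ")
    if grid[-1] - grid[0] < corr_w:
        raise ValueError("series shorter than one correlation window")

    centers, am = _bin_median(a, grid, median_w)
    _, bm = _bin_median(b, grid, median_w)

    k = max(1, int(round(smooth_w / median_w)))
    asm = pd.Series(am).rolling(k, center=True, min_periods=k).mean().to_numpy()
    bsm = pd.Series(bm).rolling(k, center=True, min_periods=k).mean().to_numpy()

    m = max(2, int(round(corr_w / median_w)))
    n = len(centers)
    r = np.full(n, np.nan)
    n_eff = np.zeros(n, dtype=int)
    for i in range(m - 1, n):
        xa = asm[i - m + 1:i + 1]
        xb = bsm[i - m + 1:i + 1]
        if np.any(np.isnan(xa)) or np.any(np.isnan(xb)):
            continue
        sa, sb = np.std(xa), np.std(xb)
        if sa == 0 or sb == 0:
            continue
        r[i] = float(np.corrcoef(xa, xb)[0, 1])
        n_eff[i] = m
    return CorrelationSeries(times=centers, r=r, n_eff=n_eff)


def rate_amp_correlations(index_series) -> dict[str, CorrelationSeries]:
    """The two standard pairs: (muPR, mu_amp) and (sigmaPR, sigma_amp)."""
    out = {}
    for name, (ca, cb) in {
        "mean": ("muPR", "mu_amp"),
        "sd": ("sigmaPR", "sigma_amp"),
    }.items():
        out[name] = sliding_rate_amp_correlation(
            index_series.channel(ca), index_series.channel(cb),
            index_series.grid)
    return out
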