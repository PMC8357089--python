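"""Instantaneous autonomic indices from fitted point-process trajectories.

Fifteen indices on a common uniform time grid: ten from heart rate
variability (muRR, sigmaRR, muHR, sigmaHR, LF, HF, LF_HF, LFnu, HFnu,
total_power) and five from electrodermal activity (tonic_EDA, muPR,
sigmaPR, mu_amp, sigma_amp).

Heart-rate moments use the exact reciprocal inverse-Gaussian moments: if
X ~ IG(mu, lam) then E[1/X] = 1/mu + 1/lam and
Var(1/X) = 1/(mu*lam) + 2/lam^2, so in beats (or pulses) per minute

    muHR    = 60 * (1/mu + 1/lam)
    sigmaHR = 60 * sqrt(1/(mu*lam) + 2/lam^2).

Frequency-domain indices come from the parametric spectrum of the AR
interval model, S(f) = sigma2 * ds / |1 - sum_i theta_i e^(-i 2 pi f i ds)|^2
with ds the instantaneous mean interval and sigma2 = mu^3/lam, integrated
over the standard LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) bands by
Gauss-Legendre quadrature.  total_power spans 0.04-0.4 Hz (the union of
the two bands; a convention, since only the bands themselves are defined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .point_process import AmpModelTrajectory, IGModelTrajectory

HRV_CHANNELS = ("muRR", "sigmaRR", "muHR", "sigmaHR", "LF", "HF",
                "LF_HF", "LFnu", "HFnu", "total_power")
EDA_CHANNELS = ("tonic_EDA", "muPR", "sigmaPR", "mu_amp", "sigma_amp")
ALL_CHANNELS = HRV_CHANNELS + EDA_CHANNELS

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass
class IndexSeries:
    """The 15 autonomic indices on a uniform grid with validity masks."""

    grid: np.ndarray
    values: pd.DataFrame        # columns = ALL_CHANNELS
    valid: pd.DataFrame         # same shape, bool

    def __post_init__(self) -> None:
        if tuple(self.values.columns) != ALL_CHANNELS:
            raise ValueError("IndexSeries must carry exactly the 15 channels")

    @property
    def delta(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def channel(self, name: str, masked: bool = True) -> np.ndarray:
        v = self.values[name].to_numpy(dtype=float, copy=True)
        if masked:
            v[~self.valid[name].to_numpy()] = np.nan
        return v


# ---------------------------------------------------------------------------
# helpers


def instantaneous_mu(traj: IGModelTrajectory,
                     events: np.ndarray) -> np.ndarray:
    """AR-predicted mean interval at every update time.

    mu(t) = theta0 + sum_i theta_i * x_(i-th most recent interval before t).
    Update times with fewer than p completed intervals are NaN.
    """
    events = np.asarray(events, dtype=float)
    intervals = np.diff(events)
    p = traj.p
    ut = traj.update_times
    if p == 0:
        return traj.theta0.copy()
    # index of last event at or before each update time
    k = np.searchsorted(events, ut, side="right") - 1
    mu = np.full(len(ut), np.nan)
    ok = k >= p            # need p completed intervals
    kk = k[ok]
    acc = traj.theta0[ok].copy()
    for i in range(1, p + 1):
        acc += traj.theta[ok, i - 1] * intervals[kk - i]
    mu[ok] = acc
    return mu


def reciprocal_ig_moments(mu, lam):
    """Exact mean and variance of 1/X for X ~ IG(mu, lam)."""
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam, dtype=float)
    mean = 1.0 / mu + 1.0 / lam
    var = 1.0 / (mu * lam) + 2.0 / lam ** 2
    return mean, var


def _ar_stable_rows(theta: np.ndarray) -> np.ndarray:
    """Row-wise AR stability via companion eigenvalues (theta: n x p)."""
    n, p = theta.shape
    if p == 0:
        return np.ones(n, dtype=bool)
    if p == 1:
        return np.abs(theta[:, 0]) < 1.0
    out = np.ones(n, dtype=bool)
    # dedupe: parameters are piecewise constant so few unique rows
    uniq, inv = np.unique(theta, axis=0, return_inverse=True)
    stab = np.empty(len(uniq), dtype=bool)
    for i, row in enumerate(uniq):
        comp = np.zeros((p, p))
        comp[0] = row
        comp[1:, :-1] = np.eye(p - 1)
        with np.errstate(all="ignore"):
            stab[i] = np.all(np.isfinite(row)) and \
                np.max(np.abs(np.linalg.eigvals(comp))) < 1.0
    return stab[inv]


def _gauss_legendre_band(lo: float, hi: float, order: int = 48):
    x, w = np.polynomial.legendre.leggauss(order)
    f = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    return f, 0.5 * (hi - lo) * w


def ar_band_powers(theta: np.ndarray, sigma2: np.ndarray, ds: np.ndarray,
                   band: tuple[float, float], order: int = 48) -> np.ndarray:
    """Integral of the AR interval spectrum over a frequency band.

    Vectorized over update times: theta (n, p), sigma2 (n,), ds (n,).
    """
    f, w = _gauss_legendre_band(*band, order=order)
    n, p = theta.shape
    if p == 0:
        return sigma2 * ds * np.sum(w)
    # denom(t, f) = |1 - sum_i theta_i exp(-i 2 pi f i ds_t)|^2
    i = np.arange(1, p + 1)
    ang = 2.0 * np.pi * np.multiply.outer(ds, f)          # (n, F)
    z = np.exp(-1j * ang[:, :, None] * i[None, None, :])   # (n, F, p)
    denom = np.abs(1.0 - np.einsum("np,nfp->nf", theta, z)) ** 2
    s = (sigma2 * ds)[:, None] / denom
    return s @ w


# ---------------------------------------------------------------------------
# index computations


def hrv_time_indices(traj: IGModelTrajectory, events: np.ndarray):
    """muRR, sigmaRR (s) and muHR, sigmaHR (bpm) at each update time."""
    mu = instantaneous_mu(traj, events)
    lam = traj.lambda_shape
    valid = traj.converged & np.isfinite(mu) & (mu > 0)
    with np.errstate(all="ignore"):
        sigma_rr = np.sqrt(mu ** 3 / lam)
        rmean, rvar = reciprocal_ig_moments(mu, lam)
        mu_hr = 60.0 * rmean
        sigma_hr = 60.0 * np.sqrt(rvar)
    out = pd.DataFrame({"muRR": mu, "sigmaRR": sigma_rr,
                        "muHR": mu_hr, "sigmaHR": sigma_hr})
    return out, valid


def hrv_spectral_indices(traj: IGModelTrajectory, events: np.ndarray,
                         quad_order: int = 48):
    """LF, HF, LF_HF, LFnu, HFnu, total_power at each update time.

    Requires p >= 1; update times with an unstable AR polynomial are
    masked.  LF_HF is masked where HF = 0.
    """
    if traj.p < 1:
        raise ValueError("spectral indices require AR order p >= 1")
    mu = instantaneous_mu(traj, events)
    lam = traj.lambda_shape
    base = traj.converged & np.isfinite(mu) & (mu > 0)
    theta = np.where(np.isfinite(traj.theta), traj.theta, 0.0)
    stable = _ar_stable_rows(theta)
    valid = base & stable
    with np.errstate(all="ignore"):
        sigma2 = mu ** 3 / lam
    ds = np.where(valid, mu, 1.0)
    s2 = np.where(valid, sigma2, 0.0)
    lf = ar_band_powers(theta, s2, ds, LF_BAND, quad_order)
    hf = ar_band_powers(theta, s2, ds, HF_BAND, quad_order)
    total = lf + hf
    with np.errstate(all="ignore"):
        lf_hf = np.where(hf > 0, lf / hf, np.nan)
        lfnu = np.where(total > 0, lf / total, np.nan)
        hfnu = np.where(total > 0, hf / total, np.nan)
    out = pd.DataFrame({"LF": lf, "HF": hf, "LF_HF": lf_hf,
                        "LFnu": lfnu, "HFnu": hfnu, "total_power": total})
    valid_df = pd.DataFrame({
        "LF": valid, "HF": valid,
        "LF_HF": valid & (hf > 0),
        "LFnu": valid & (total > 0), "HFnu": valid & (total > 0),
        "total_power": valid,
    })
    return out, valid_df


def eda_indices(ig_traj: IGModelTrajectory, amp_traj: AmpModelTrajectory,
                pulse_times: np.ndarray, pulse_amps: np.ndarray,
                tonic_times: np.ndarray, tonic_values: np.ndarray):
    """tonic_EDA, muPR, sigmaPR (pulses/min), mu_amp, sigma_amp (uS).

    The two trajectories must share their update grid.  Pulse-rate
    moments reuse the reciprocal-IG formulas on inter-pulse intervals;
    mu_amp is the AR-predicted instantaneous mean amplitude.
    """
    if len(ig_traj.update_times) != len(amp_traj.update_times) or \
            not np.allclose(ig_traj.update_times, amp_traj.update_times):
        raise ValueError("interval and amplitude trajectories must share grid")
    ut = ig_traj.update_times
    mu = instantaneous_mu(ig_traj, pulse_times)
    lam = ig_traj.lambda_shape
    v_rate = ig_traj.converged & np.isfinite(mu) & (mu > 0)
    with np.errstate(all="ignore"):
        rmean, rvar = reciprocal_ig_moments(mu, lam)
        mu_pr = 60.0 * rmean
        sigma_pr = 60.0 * np.sqrt(rvar)

    # instantaneous AR-predicted amplitude mean
    q = amp_traj.q
    amps = np.asarray(pulse_amps, dtype=float)
    k = np.searchsorted(np.asarray(pulse_times, float), ut, side="right") - 1
    mu_amp = np.full(len(ut), np.nan)
    ok = k >= q - 1 if q > 0 else k >= -1
    kk = np.clip(k, 0, None)
    acc = amp_traj.alpha0.copy()
    for i in range(1, q + 1):
        lagged = np.where(kk - (i - 1) >= 0, amps[np.clip(kk - (i - 1), 0, None)],
                          np.nan)
        acc = acc + amp_traj.alpha[:, i - 1] * lagged
    mu_amp[ok] = acc[ok]
    v_amp = amp_traj.converged & np.isfinite(mu_amp)
    with np.errstate(all="ignore"):
        sigma_amp = np.sqrt(np.clip(amp_traj.sigma2, 0.0, None))

    tonic = np.interp(ut, tonic_times, tonic_values) \
        if len(tonic_times) else np.full(len(ut), np.nan)
    v_tonic = np.isfinite(tonic)

    out = pd.DataFrame({"tonic_EDA": tonic, "muPR": mu_pr,
                        "sigmaPR": sigma_pr, "mu_amp": mu_amp,
                        "sigma_amp": sigma_amp})
    valid_df = pd.DataFrame({
        "tonic_EDA": v_tonic, "muPR": v_rate, "sigmaPR": v_rate,
        "mu_amp": v_amp, "sigma_amp": amp_traj.converged,
    })
    return out, valid_df


def assemble_index_series(hrv_values: pd.DataFrame, hrv_valid,
                          hrv_grid: np.ndarray,
                          eda_values: pd.DataFrame, eda_valid,
                          eda_grid: np.ndarray) -> IndexSeries:
    """Join HRV and EDA channels on the intersection of their grids.

    Both grids must share the same spacing and phase; disjoint supports
    are an error.  Exactly the 15 named channels come out.
    """
    d1 = hrv_grid[1] - hrv_grid[0]
    d2 = eda_grid[1] - eda_grid[0]
    if not np.isclose(d1, d2):
        raise ValueError("HRV and EDA grids have different spacing")
    offset = (eda_grid[0] - hrv_grid[0]) / d1
    if not np.isclose(offset, np.round(offset), atol=1e-6):
        raise ValueError("HRV and EDA grids are out of phase")
    lo = max(hrv_grid[0], eda_grid[0])
    hi = min(hrv_grid[-1], eda_grid[-1])
    if hi < lo:
        raise ValueError("HRV and EDA grids have disjoint support")
    grid = hrv_grid[(hrv_grid >= lo - 1e-9) & (hrv_grid <= hi + 1e-9)]

    def subset(values, valid, g):
        i0 = int(np.round((lo - g[0]) / d1))
        sl = slice(i0, i0 + len(grid))
        if isinstance(valid, pd.DataFrame):
            return values.iloc[sl].reset_index(drop=True), \
                valid.iloc[sl].reset_index(drop=True)
        return values.iloc[sl].reset_index(drop=True), \
            pd.DataFrame({c: np.asarray(valid)[sl] for c in values.columns})

    hv, hm = subset(hrv_values, hrv_valid, hrv_grid)
    ev, em = subset(eda_values, eda_valid, eda_grid)
    values = pd.concat([hv, ev], axis=1)[list(ALL_CHANNELS)]
    valid = pd.concat([hm, em], axis=1)[list(ALL_CHANNELS)]
    return IndexSeries(grid=grid, values=values, valid=valid.astype(bool))


def compute_hrv_index_block(traj: IGModelTrajectory, events: np.ndarray):
    """All ten HRV channels (values, valid, grid) for assembly."""
    tvals, tvalid = hrv_time_indices(traj, events)
    svals, svalid = hrv_spectral_indices(traj, events)
    values = pd.concat([tvals, svals], axis=1)[list(HRV_CHANNELS)]
    valid = pd.concat(
        [pd.DataFrame({c: tvalid for c in tvals.columns}), svalid],
        axis=1)[list(HRV_CHANNELS)]
    return values, valid, traj.update_times
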