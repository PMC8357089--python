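"""History-dependent inverse-Gaussian point-process models.

The statistical engine of the package: inter-event intervals (RR intervals
from the ECG, or inter-pulse intervals in phasic electrodermal activity) are
modeled as inverse-Gaussian (IG) with a history-dependent mean,

    x_j ~ IG(mu_j, lambda),    mu_j = theta0 + sum_i theta_i * x_{j-i},

the integrate-and-fire interpretation of pacemaker/sudomotor dynamics.
Parameters are estimated by local maximum likelihood on non-overlapping
time windows, giving a piecewise-constant trajectory of (theta, lambda)
whose instantaneous transforms are the autonomic indices.  A parallel
history-dependent Gaussian model describes EDA pulse amplitudes.
Goodness of fit uses the probability integral transform (time rescaling)
and a Kolmogorov-Smirnov test against Uniform(0,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

LAMBDA_CAP = 1e8
_LOG_2PI = np.log(2.0 * np.pi)

# default screening grids: AR orders 1..8, window lengths 60/90/120 s
DEFAULT_P_GRID = tuple(range(1, 9))
DEFAULT_W_GRID = (60.0, 90.0, 120.0)


# ---------------------------------------------------------------------------
# configuration and result containers


@dataclass(frozen=True)
class IGModelConfig:
    """Hyperparameters of the local-likelihood IG interval model.

    Parameters
    ----------
    p : autoregressive order of the history-dependent mean (>= 0).
    W_fit : local-likelihood window length in seconds (non-overlapping).
    delta : spacing of the uniform update grid in seconds.
    censor_last : if True, the final partial interval of each window
        contributes a right-censored survival term to the likelihood.
    """

    p: int = 1
    W_fit: float = 60.0
    delta: float = 0.25
    censor_last: bool = False

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("AR order p must be >= 0")
        if self.W_fit <= 0 or self.delta <= 0:
            raise ValueError("W_fit and delta must be positive")
        if self.W_fit < self.delta:
            raise ValueError("W_fit must be >= delta")


@dataclass
class IGModelTrajectory:
    """Piecewise-constant IG parameter trajectory on a uniform update grid.

    ``update_times`` has spacing ``cfg.delta``; entries earlier than the
    first full fitting window carry no estimates (``converged`` False):
    the first window of each dataset is consumed fitting parameters.
    ``window_starts``/``window_params`` expose the underlying per-window
    fits (columns: theta0, theta_1..p, lambda).
    """

    cfg: IGModelConfig
    update_times: np.ndarray
    theta0: np.ndarray
    theta: np.ndarray          # shape (n_updates, p)
    lambda_shape: np.ndarray
    converged: np.ndarray      # bool per update
    window_starts: np.ndarray = field(default=None)
    window_params: np.ndarray = field(default=None)     # (n_windows, p + 2)
    window_converged: np.ndarray = field(default=None)

    @property
    def p(self) -> int:
        return self.cfg.p


@dataclass
class AmpModelTrajectory:
    """History-dependent Gaussian amplitude model on the same update grid."""

    q: int
    update_times: np.ndarray
    alpha0: np.ndarray
    alpha: np.ndarray          # (n_updates, q)
    sigma2: np.ndarray
    converged: np.ndarray
    window_starts: np.ndarray = field(default=None)
    window_params: np.ndarray = field(default=None)     # (n_windows, q + 2)
    window_converged: np.ndarray = field(default=None)


@dataclass
class GofReport:
    """PIT / Kolmogorov-Smirnov goodness-of-fit summary."""

    pit_values: np.ndarray
    ks_stat: float
    ks_band: float
    n: int

    @property
    def passed(self) -> bool:
        return bool(self.ks_stat <= self.ks_band)


# ---------------------------------------------------------------------------
# density


def ig_logpdf(x, mu, lam):
    """Log-density of the inverse Gaussian at interval ``x``.

    log f(x) = 1/2 log(lam / (2 pi x^3)) - lam (x - mu)^2 / (2 mu^2 x)

    All arguments broadcast; every element must be strictly positive.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(x <= 0) or np.any(mu <= 0) or np.any(lam <= 0):
        raise ValueError("ig_logpdf requires x > 0, mu > 0, lam > 0")
    return 0.5 * (np.log(lam) - _LOG_2PI - 3.0 * np.log(x)) \
        - lam * (x - mu) ** 2 / (2.0 * mu ** 2 * x)


def ig_cdf(x, mu, lam):
    """Inverse-Gaussian CDF (mean ``mu``, shape ``lam``)."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam, dtype=float)
    # scipy's invgauss is shape-1; X/lam ~ invgauss(mu/lam) has mean mu, shape lam
    return stats.invgauss.cdf(x / lam, mu / lam)


def ig_sf(x, mu, lam):
    x = np.asarray(x, dtype=float)
    return stats.invgauss.sf(x / lam, np.asarray(mu, float) / lam)


# ---------------------------------------------------------------------------
# local-likelihood fitting


def _design(intervals: np.ndarray, p: int):
    """Regression targets/design for the AR mean over a full interval series.

    Row j predicts intervals[j] from the p preceding intervals; the first p
    intervals are burn-in.  Returns (y, X) with X including the intercept.
    """
    n = len(intervals)
    if n <= p:
        return np.empty(0), np.empty((0, p + 1))
    y = intervals[p:]
    X = np.ones((n - p, p + 1))
    for i in range(1, p + 1):
        X[:, i] = intervals[p - i:n - i]
    return y, X


def _ig_nll_grad(params, y, X, censored=None):
    """Negative log-likelihood and gradient in (theta, log lam).

    Infeasible mean (mu <= 0 anywhere) returns a large penalty so the
    line search backtracks.
    """
    theta = params[:-1]
    nu = params[-1]
    lam = np.exp(nu)
    mu = X @ theta
    if np.any(mu <= 1e-8):
        return 1e12 * (1.0 + float(np.sum(np.minimum(mu, 0.0) ** 2))), \
            np.zeros_like(params)
    r = y - mu
    q = r ** 2 / (2.0 * mu ** 2 * y)
    nll = -np.sum(0.5 * (nu - _LOG_2PI - 3.0 * np.log(y)) - lam * q)
    # d logf / d mu = lam (x - mu) / mu^3
    dl_dmu = lam * r / mu ** 3
    g_theta = -(X.T @ dl_dmu)
    g_nu = -np.sum(0.5 - lam * q)
    if censored is not None:
        xc, Xc = censored
        muc = Xc @ theta
        if np.any(muc <= 1e-8):
            return 1e12, np.zeros_like(params)
        sf = np.clip(stats.invgauss.sf(xc / lam, muc / lam), 1e-300, None)
        nll -= float(np.sum(np.log(sf)))
        eps = 1e-6
        # numeric gradient for the (single, rarely used) censored term
        gnum = np.zeros_like(params)
        for k in range(len(params)):
            pp = params.copy()
            pp[k] += eps
            th, nv = pp[:-1], pp[-1]
            m2 = Xc @ th
            sf2 = np.clip(stats.invgauss.sf(xc / np.exp(nv), m2 / np.exp(nv)),
                          1e-300, None)
            gnum[k] = -(np.sum(np.log(sf2)) - np.sum(np.log(sf))) / eps
        g_theta = g_theta + gnum[:-1]
        g_nu = g_nu + gnum[-1]
    g = np.append(g_theta, g_nu)
    return float(nll), g


def _fit_ig_window(y, X, censored=None):
    """Maximize the IG local likelihood for one window.

    Returns (theta0, theta_1..p, lambda, converged).  Near-constant
    intervals trip a zero-variance guard: theta0 = mean, lambda capped.
    """
    p = X.shape[1] - 1
    m = float(np.mean(y))
    v = float(np.var(y))
    if v < 1e-14 * max(m, 1.0) ** 2:
        out = np.zeros(p + 2)
        out[0] = m
        out[-1] = LAMBDA_CAP
        return out, True
    lam0 = min(m ** 3 / v, LAMBDA_CAP)
    x0 = np.zeros(p + 2)
    x0[0] = m
    x0[-1] = np.log(lam0)
    bounds = [(None, None)] * (p + 1) + [(-10.0, np.log(LAMBDA_CAP))]
    res = optimize.minimize(
        _ig_nll_grad, x0, args=(y, X, censored), jac=True,
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-10},
    )
    params = np.empty(p + 2)
    params[:-1] = res.x[:-1]
    params[-1] = np.exp(res.x[-1])
    ok = bool(res.success) and np.isfinite(res.fun)
    return params, ok


def fit_ig_local(events: np.ndarray, cfg: IGModelConfig) -> IGModelTrajectory:
    """Fit the history-dependent IG model on non-overlapping windows.

    Windows are [k*W_fit, (k+1)*W_fit) from the first event; a window's
    likelihood uses the intervals *ending* inside it, each with its p
    preceding intervals as history.  Fitted parameters are held constant
    for every update time in the window.  Update times earlier than one
    full window after the start carry no estimates.

    Raises ``ValueError`` if the recording is shorter than one window.
    Windows with fewer than p + 2 intervals are flagged non-converged.
    """
    events = np.asarray(events, dtype=float)
    if len(events) < 2:
        raise ValueError("need at least two events")
    t0, t1 = float(events[0]), float(events[-1])
    duration = t1 - t0
    if duration < cfg.W_fit:
        raise ValueError("recording shorter than one fitting window")
    intervals = np.diff(events)
    ends = events[1:]          # time each interval ends
    p = cfg.p

    n_windows = int(np.floor(duration / cfg.W_fit))
    window_starts = t0 + cfg.W_fit * np.arange(n_windows)
    window_params = np.full((n_windows, p + 2), np.nan)
    window_ok = np.zeros(n_windows, dtype=bool)

    y_all, X_all = _design(intervals, p)
    ends_all = ends[p:]
    for k in range(n_windows):
        lo = window_starts[k]
        hi = lo + cfg.W_fit
        sel = (ends_all >= lo) & (ends_all < hi)
        y = y_all[sel]
        X = X_all[sel]
        if len(y) < p + 2:
            continue
        censored = None
        if cfg.censor_last:
            # partial interval open at the window end
            last_idx = np.flatnonzero(sel)
            if len(last_idx):
                j = last_idx[-1]
                open_x = hi - ends_all[j]
                if open_x > 0 and j + 1 < len(y_all):
                    censored = (np.array([open_x]), X_all[j + 1:j + 2])
        params, ok = _fit_ig_window(y, X, censored)
        window_params[k] = params
        window_ok[k] = ok

    # update grid on absolute multiples of delta so channels share phase
    g0 = np.ceil(t0 / cfg.delta - 1e-9) * cfg.delta
    n_up = int(np.floor((t1 - g0) / cfg.delta + 1e-9)) + 1
    update_times = g0 + cfg.delta * np.arange(n_up)
    widx = np.minimum((np.floor((update_times - t0) / cfg.W_fit)).astype(int),
                      n_windows - 1)
    theta0 = window_params[widx, 0]
    theta = window_params[widx, 1:p + 1] if p > 0 else np.zeros((n_up, 0))
    lam = window_params[widx, -1]
    conv = window_ok[widx] & (update_times >= t0 + cfg.W_fit)
    return IGModelTrajectory(
        cfg=cfg, update_times=update_times, theta0=theta0, theta=theta,
        lambda_shape=lam, converged=conv,
        window_starts=window_starts, window_params=window_params,
        window_converged=window_ok,
    )


def fit_amp_local(pulse_times: np.ndarray, amplitudes: np.ndarray,
                  q: int = 1, W_fit: float = 300.0, delta: float = 0.25,
                  update_times: np.ndarray | None = None) -> AmpModelTrajectory:
    """Fit the history-dependent Gaussian pulse-amplitude model.

    Per-window conditional maximum likelihood = OLS of a_j on its q lagged
    amplitudes, sigma^2 = RSS / n.  If ``update_times`` is given the
    trajectory is emitted on that grid (shared with the interval model),
    otherwise on a fresh grid of spacing ``delta``.
    """
    t = np.asarray(pulse_times, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if len(t) != len(a):
        raise ValueError("times and amplitudes must have equal length")
    if len(t) < 2:
        raise ValueError("need at least two pulses")
    t0, t1 = float(t[0]), float(t[-1])
    duration = t1 - t0
    if duration < W_fit:
        raise ValueError("recording shorter than one fitting window")

    n_windows = int(np.floor(duration / W_fit))
    window_starts = t0 + W_fit * np.arange(n_windows)
    window_params = np.full((n_windows, q + 2), np.nan)
    window_ok = np.zeros(n_windows, dtype=bool)

    n = len(a)
    if n > q:
        y_all = a[q:]
        X_all = np.ones((n - q, q + 1))
        for i in range(1, q + 1):
            X_all[:, i] = a[q - i:n - i]
        t_all = t[q:]
        for k in range(n_windows):
            lo = window_starts[k]
            hi = lo + W_fit
            sel = (t_all >= lo) & (t_all < hi)
            y = y_all[sel]
            X = X_all[sel]
            if len(y) < q + 2:
                continue
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ coef) ** 2))
            window_params[k, :q + 1] = coef
            window_params[k, -1] = rss / len(y)
            window_ok[k] = True

    if update_times is None:
        g0 = np.ceil(t0 / delta - 1e-9) * delta
        n_up = int(np.floor((t1 - g0) / delta + 1e-9)) + 1
        update_times = g0 + delta * np.arange(n_up)
    update_times = np.asarray(update_times, dtype=float)
    widx = np.clip((np.floor((update_times - t0) / W_fit)).astype(int),
                   0, n_windows - 1)
    in_support = (update_times >= t0 + W_fit) & (update_times <= t1 + W_fit)
    alpha0 = np.where(in_support, window_params[widx, 0], np.nan)
    alpha = window_params[widx, 1:q + 1] if q > 0 \
        else np.zeros((len(update_times), 0))
    sigma2 = np.where(in_support, window_params[widx, -1], np.nan)
    conv = window_ok[widx] & in_support
    return AmpModelTrajectory(
        q=q, update_times=update_times, alpha0=alpha0, alpha=alpha,
        sigma2=sigma2, converged=conv,
        window_starts=window_starts, window_params=window_params,
        window_converged=window_ok,
    )


# ---------------------------------------------------------------------------
# goodness of fit


def pit_ks_gof(events: np.ndarray, traj: IGModelTrajectory) -> GofReport:
    """Time-rescaling goodness of fit via the probability integral transform.

    Each observed interval is pushed through the fitted IG CDF at its end
    time; under a correct model the transforms are iid Uniform(0,1).  The
    KS statistic is compared with the asymptotic 95% band 1.36/sqrt(n).
    """
    events = np.asarray(events, dtype=float)
    intervals = np.diff(events)
    ends = events[1:]
    p = traj.p
    y, X = _design(intervals, p)
    ends = ends[p:]
    # map each interval end to its window parameters
    wi = np.searchsorted(traj.window_starts, ends, side="right") - 1
    wi = np.clip(wi, 0, len(traj.window_starts) - 1)
    ok = traj.window_converged[wi] & \
        (ends >= traj.window_starts[0] + traj.cfg.W_fit)
    if np.sum(ok) < 20:
        raise ValueError("fewer than 20 usable events for goodness of fit")
    params = traj.window_params[wi[ok]]
    mu = np.sum(X[ok] * params[:, :p + 1], axis=1)
    lam = params[:, -1]
    usable = mu > 0
    u = ig_cdf(y[ok][usable], mu[usable], lam[usable])
    u = np.clip(u, 0.0, 1.0)
    n = len(u)
    us = np.sort(u)
    j = np.arange(1, n + 1)
    ks = float(max(np.max(j / n - us), np.max(us - (j - 1) / n)))
    band = 1.36 / np.sqrt(n)
    return GofReport(pit_values=u, ks_stat=ks, ks_band=band, n=n)


def pit_ks_uniform(u: np.ndarray) -> tuple[float, float]:
    """KS statistic of given PIT values against Uniform(0,1), with 95% band."""
    u = np.sort(np.asarray(u, dtype=float))
    n = len(u)
    j = np.arange(1, n + 1)
    ks = float(max(np.max(j / n - u), np.max(u - (j - 1) / n)))
    return ks, 1.36 / np.sqrt(n)


# ---------------------------------------------------------------------------
# hyperparameter screening


def screen_hyperparams(events: np.ndarray, p_grid=DEFAULT_P_GRID,
                       W_grid=DEFAULT_W_GRID,
                       delta: float = 0.25) -> IGModelConfig:
    """Select (p, W_fit) by minimum KS statistic over the grid.

    Ties break toward smaller p then smaller W_fit.  Raises if every
    combination fails to fit.
    """
    p_grid = list(p_grid)
    W_grid = list(W_grid)
    if not p_grid or not W_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    best = None
    for p in sorted(p_grid):
        for W in sorted(W_grid):
            cfg = IGModelConfig(p=p, W_fit=W, delta=delta)
            try:
                traj = fit_ig_local(events, cfg)
                rep = pit_ks_gof(events, traj)
            except ValueError:
                continue
            if best is None or rep.ks_stat < best[0] - 1e-15:
                best = (rep.ks_stat, cfg)
    if best is None:
        raise ValueError("no hyperparameter combination converged")
    return best[1]
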