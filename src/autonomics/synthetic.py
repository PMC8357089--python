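"""Synthetic propofol-session generator.

Emulates the structure of a target-controlled propofol infusion study:
nine subjects, ten infusion stages of roughly 15 minutes targeting
0, 1, 2, 3, 4, 5, 3.75, 2.5, 1.25, 0 mg/kg/hr, behavioral loss and
recovery of consciousness (LOC/ROC) annotated from a button-press task,
and continuous ECG + electrodermal activity (EDA).

Event trains are drawn from the same family the analysis fits: intervals
are inverse Gaussian with an autoregressive mean, EDA pulse amplitudes
follow a history-dependent Gaussian, and tonic EDA drifts slowly.  The
conscious and unconscious autonomic regimes are blended through logistic
gates centered at LOC/ROC, shifted per subject by a signed autonomic
lead/lag, and modulated by the stage-driven drug-effect level.  Ground
truth (per-time blended parameters) is retained so downstream estimators
can be checked for recovery.

Default regime magnitudes are package constants chosen to match the
qualitative pharmacology (propofol is a myocardial depressant and raises
sweating thresholds): RR interval lengthens 0.85 -> 1.00 s, EDA pulse
rate drops ~8/min -> ~2/min, pulse amplitudes halve, tonic EDA sags.
They are not measured values and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RegimeParams:
    """Stationary parameters of one autonomic regime for one channel.

    ``mu_base`` is the stationary mean interval; the AR intercept is
    derived as mu_base * (1 - sum(ar_coeffs)) so the long-run mean stays
    at mu_base for any stable AR history.  Amplitude fields are used only
    for the EDA channel.
    """

    mu_base: float                      # mean interval, s
    ar_coeffs: tuple = ()               # theta_1..p on past intervals
    lambda_shape: float = 1000.0        # IG shape, s
    amp_mean: float = 0.0               # stationary pulse amplitude, uS
    amp_ar: tuple = ()                  # alpha_1..q on past amplitudes
    amp_sd: float = 0.0                 # amplitude innovation SD, uS
    tonic_level: float = 0.0            # tonic EDA, uS

    def __post_init__(self) -> None:
        if self.mu_base <= 0:
            raise ValueError("mu_base must be positive")
        if self.lambda_shape <= 0:
            raise ValueError("lambda_shape must be positive")
        if self.amp_sd < 0:
            raise ValueError("amp_sd must be non-negative")
        for coeffs in (self.ar_coeffs, self.amp_ar):
            if coeffs and not _ar_stable(coeffs):
                raise ValueError(f"unstable AR coefficients {coeffs}")

    @property
    def theta0(self) -> float:
        return self.mu_base * (1.0 - sum(self.ar_coeffs))

    @property
    def alpha0(self) -> float:
        return self.amp_mean * (1.0 - sum(self.amp_ar))


def _ar_stable(coeffs) -> bool:
    """All companion-matrix eigenvalues strictly inside the unit circle."""
    c = np.asarray(coeffs, dtype=float)
    if c.size == 0:
        return True
    if c.size == 1:
        return bool(abs(c[0]) < 1.0)
    comp = np.zeros((c.size, c.size))
    comp[0] = c
    if c.size > 1:
        comp[1:, :-1] = np.eye(c.size - 1)
    return bool(np.max(np.abs(np.linalg.eigvals(comp))) < 1.0)


def _blend(a: RegimeParams, b: RegimeParams, w: float) -> RegimeParams:
    """Convex combination of two regimes (w = weight of b)."""
    def mix(x, y):
        return (1.0 - w) * x + w * y
    return RegimeParams(
        mu_base=mix(a.mu_base, b.mu_base),
        ar_coeffs=tuple(mix(np.asarray(a.ar_coeffs, float),
                            np.asarray(b.ar_coeffs, float))
                        ) if a.ar_coeffs else (),
        lambda_shape=mix(a.lambda_shape, b.lambda_shape),
        amp_mean=mix(a.amp_mean, b.amp_mean),
        amp_ar=tuple(mix(np.asarray(a.amp_ar, float),
                         np.asarray(b.amp_ar, float))) if a.amp_ar else (),
        amp_sd=mix(a.amp_sd, b.amp_sd),
        tonic_level=mix(a.tonic_level, b.tonic_level),
    )


# default infusion-stage targets, mg/kg/hr
STAGE_TARGETS_MG_KG_HR = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 3.75, 2.5, 1.25, 0.0)

CONSCIOUS_RR = RegimeParams(mu_base=0.85, ar_coeffs=(0.3,),
                            lambda_shape=900.0)
UNCONSCIOUS_RR = RegimeParams(mu_base=1.00, ar_coeffs=(0.3,),
                              lambda_shape=2500.0)
CONSCIOUS_EDA = RegimeParams(mu_base=7.5, ar_coeffs=(0.2,),
                             lambda_shape=30.0, amp_mean=0.5,
                             amp_ar=(0.3,), amp_sd=0.10, tonic_level=6.0)
UNCONSCIOUS_EDA = RegimeParams(mu_base=30.0, ar_coeffs=(0.2,),
                               lambda_shape=120.0, amp_mean=0.25,
                               amp_ar=(0.3,), amp_sd=0.05, tonic_level=4.0)


@dataclass(frozen=True)
class SyntheticSessionSpec:
    """Study-design parameters for a batch of synthetic sessions."""

    n_subjects: int = 9
    stage_minutes: float = 15.0
    stage_targets: tuple = STAGE_TARGETS_MG_KG_HR
    conscious_rr: RegimeParams = CONSCIOUS_RR
    unconscious_rr: RegimeParams = UNCONSCIOUS_RR
    conscious_eda: RegimeParams = CONSCIOUS_EDA
    unconscious_eda: RegimeParams = UNCONSCIOUS_EDA
    loc_time: float = 40.0 * 60.0
    roc_time: float = 130.0 * 60.0
    autonomic_lag_range: tuple = (-180.0, 180.0)   # per-subject Uniform draw, s
    transition_halfwidth: float = 120.0
    effect_scale: float = 1.0       # scales regime separation (1 = full)
    amp_floor: float = 0.01         # truncation floor for amplitudes, uS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loc_time >= self.roc_time:
            raise ValueError("loc_time must precede roc_time")
        if self.stage_minutes <= 0:
            raise ValueError("stage_minutes must be positive")
        if not (0 <= self.effect_scale):
            raise ValueError("effect_scale must be non-negative")

    @property
    def duration(self) -> float:
        return self.stage_minutes * 60.0 * len(self.stage_targets)


@dataclass(frozen=True)
class SessionAnnotations:
    """Behavioral annotations and infusion-stage bookkeeping."""

    loc_s: float
    roc_s: float
    baseline_pre: tuple      # [start, end) s
    baseline_post: tuple
    stage_starts: tuple
    stage_targets: tuple
    duration: float

    def __post_init__(self) -> None:
        if self.loc_s >= self.roc_s:
            raise ValueError("loc_s must precede roc_s")


@dataclass
class SyntheticSession:
    """One subject's synthetic recording with ground truth."""

    subject_id: str
    r_peaks: np.ndarray
    eda_pulse_times: np.ndarray
    eda_pulse_amps: np.ndarray
    tonic_times: np.ndarray
    tonic_values: np.ndarray
    annotations: SessionAnnotations
    truth: pd.DataFrame          # per-second blended parameters
    autonomic_lag: float


# ---------------------------------------------------------------------------
# low-level samplers


def simulate_ig_train(param_fn, duration: float, seed: int,
                      max_events: int = 2_000_000) -> np.ndarray:
    """Sample an event train with IG intervals and an AR history mean.

    ``param_fn(t)`` returns the RegimeParams in force at time t.  Each
    interval is drawn from IG(mu_j, lambda) with
    mu_j = theta0 + sum_i theta_i * x_{j-i}; the history is initialized
    at the local mu_base.  Events strictly increase and never exceed
    ``duration``.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    rng = np.random.default_rng(seed)
    events = []
    t = 0.0
    history: list[float] = []
    while t <= duration:
        pars = param_fn(t)
        if pars.ar_coeffs and not _ar_stable(pars.ar_coeffs):
            raise ValueError(f"unstable AR coefficients at t={t:.1f}s")
        p = len(pars.ar_coeffs)
        while len(history) < p:
            history.insert(0, pars.mu_base)
        mu = pars.theta0 + float(
            np.dot(pars.ar_coeffs, history[-1:-p - 1:-1])) if p else pars.mu_base
        if mu <= 0:
            raise ValueError(
                f"non-positive interval mean mu={mu:.4g} at t={t:.1f}s")
        x = float(rng.wald(mu, pars.lambda_shape))
        t += x
        if t > duration:
            break
        events.append(t)
        history.append(x)
        if len(events) > max_events:
            raise RuntimeError("event budget exceeded; check parameters")
    return np.asarray(events)


def simulate_amplitudes(amp_param_fn, pulse_times: np.ndarray, seed: int,
                        floor: float = 0.01) -> np.ndarray:
    """Draw history-dependent Gaussian amplitudes for given pulse times.

    a_j ~ Normal(alpha0 + sum_i alpha_i a_{j-i}, sigma^2), clamped below
    at ``floor`` (> 0) rather than rejection-sampled; at default noise
    levels the truncation bias is negligible.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    if len(pulse_times) == 0:
        return np.empty(0)
    if np.any(np.diff(pulse_times) <= 0):
        raise ValueError("pulse_times must be strictly increasing")
    rng = np.random.default_rng(seed)
    amps = np.empty(len(pulse_times))
    history: list[float] = []
    for j, t in enumerate(pulse_times):
        pars = amp_param_fn(t)
        q = len(pars.amp_ar)
        while len(history) < q:
            history.insert(0, pars.amp_mean)
        mean = pars.alpha0 + float(
            np.dot(pars.amp_ar, history[-1:-q - 1:-1])) if q else pars.amp_mean
        a = mean + pars.amp_sd * float(rng.standard_normal())
        a = max(a, floor)
        amps[j] = a
        history.append(a)
    return amps


# ---------------------------------------------------------------------------
# session assembly


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _effect_weight(t, spec: SyntheticSessionSpec, lag: float):
    """Blend weight of the unconscious regime at time(s) t, in [0, 1].

    Logistic gates open after LOC and close after ROC (both shifted by the
    subject's autonomic lag); inside the gate the weight is modulated by
    the normalized stage target so deeper infusion stages sit closer to
    the fully unconscious regime.
    """
    t = np.asarray(t, dtype=float)
    hw = spec.transition_halfwidth
    tl = spec.loc_time + lag
    tr = spec.roc_time + lag
    gate = _sigmoid((t - tl) / hw) * _sigmoid(-(t - tr) / hw)
    targets = np.asarray(spec.stage_targets, dtype=float)
    peak = targets.max() if targets.max() > 0 else 1.0
    idx = np.clip((t // (spec.stage_minutes * 60.0)).astype(int),
                  0, len(targets) - 1)
    depth = targets[idx] / peak
    return spec.effect_scale * gate * (0.7 + 0.3 * depth)


def simulate_session(spec: SyntheticSessionSpec,
                     subject_idx: int) -> SyntheticSession:
    """Generate one subject's full synthetic session.

    All randomness derives from (spec.seed, subject_idx); identical calls
    are bit-identical.  The per-subject autonomic lag is drawn from
    Uniform(autonomic_lag_range).
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(spec.seed), int(subject_idx), 7919]))
    lag = float(rng.uniform(*spec.autonomic_lag_range))
    dur = spec.duration
    if not (0 < spec.loc_time + lag < dur and 0 < spec.roc_time + lag < dur):
        raise ValueError("autonomic lag pushes a transition outside session")

    def rr_fn(t):
        return _blend(spec.conscious_rr, spec.unconscious_rr,
                      float(_effect_weight(t, spec, lag)))

    def eda_fn(t):
        return _blend(spec.conscious_eda, spec.unconscious_eda,
                      float(_effect_weight(t, spec, lag)))

    seeds = rng.integers(0, 2 ** 31 - 1, size=4)
    r_peaks = simulate_ig_train(rr_fn, dur, int(seeds[0]))
    pulse_times = simulate_ig_train(eda_fn, dur, int(seeds[1]))
    pulse_amps = simulate_amplitudes(eda_fn, pulse_times, int(seeds[2]),
                                     floor=spec.amp_floor)

    # tonic: blended level + slow sinusoid + smoothed noise, 1 Hz grid
    tt = np.arange(0.0, dur + 1.0)
    w = _effect_weight(tt, spec, lag)
    level = (1 - w) * spec.conscious_eda.tonic_level \
        + w * spec.unconscious_eda.tonic_level
    rng_t = np.random.default_rng(int(seeds[3]))
    phase = rng_t.uniform(0, 2 * np.pi)
    slow = 0.3 * np.sin(2 * np.pi * tt / 1200.0 + phase)
    noise = rng_t.standard_normal(len(tt))
    kernel = np.exp(-np.arange(0, 120.0) / 30.0)
    kernel /= kernel.sum()
    smooth_noise = 0.05 * np.convolve(noise, kernel, mode="same")
    tonic = np.clip(level + slow + smooth_noise, 0.05, None)

    stage_starts = tuple(spec.stage_minutes * 60.0 * k
                         for k in range(len(spec.stage_targets)))
    ann = SessionAnnotations(
        loc_s=spec.loc_time, roc_s=spec.roc_time,
        baseline_pre=(0.0, stage_starts[1]),
        baseline_post=(stage_starts[-1], dur),
        stage_starts=stage_starts, stage_targets=tuple(spec.stage_targets),
        duration=dur,
    )

    grid = np.arange(0.0, dur + 1.0, 1.0)
    wg = _effect_weight(grid, spec, lag)
    truth = pd.DataFrame({
        "time_s": grid,
        "effect_weight": wg,
        "rr_mu": (1 - wg) * spec.conscious_rr.mu_base
        + wg * spec.unconscious_rr.mu_base,
        "rr_lambda": (1 - wg) * spec.conscious_rr.lambda_shape
        + wg * spec.unconscious_rr.lambda_shape,
        "eda_mu": (1 - wg) * spec.conscious_eda.mu_base
        + wg * spec.unconscious_eda.mu_base,
        "eda_amp_mean": (1 - wg) * spec.conscious_eda.amp_mean
        + wg * spec.unconscious_eda.amp_mean,
        "tonic_level": level[np.clip(grid.astype(int), 0, len(level) - 1)],
    })

    return SyntheticSession(
        subject_id=f"S{subject_idx + 1:02d}",
        r_peaks=r_peaks,
        eda_pulse_times=pulse_times,
        eda_pulse_amps=pulse_amps,
        tonic_times=tt,
        tonic_values=tonic,
        annotations=ann,
        truth=truth,
        autonomic_lag=lag,
    )


def simulate_study(spec: SyntheticSessionSpec) -> list[SyntheticSession]:
    """All subjects of the study design (independent per-subject seeds)."""
    return [simulate_session(spec, i) for i in range(spec.n_subjects)]


# ---------------------------------------------------------------------------
# waveform rendering (for preprocessing tests)


def _qrs_template(fs: float, width_s: float = 0.02):
    """Stereotyped QRS-like wavelet: Gaussian second derivative, unit peak."""
    half = int(round(0.06 * fs))
    t = np.arange(-half, half + 1) / fs
    z = t / width_s
    w = (1 - z ** 2) * np.exp(-z ** 2 / 2.0)
    return w / w.max()


def render_ecg(r_peaks: np.ndarray, duration: float, fs: float = 250.0,
               noise_sd: float = 0.0, amplitude: float = 1.0,
               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render a schematic ECG: a QRS template at each R time plus noise.

    Returns (times, values).  P/T waves are deliberately absent; the
    waveform exists to exercise R-peak detection against ground truth.
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz for ECG rendering")
    n = int(round(duration * fs)) + 1
    x = np.zeros(n)
    tpl = _qrs_template(fs)
    half = (len(tpl) - 1) // 2
    for tp in np.asarray(r_peaks, dtype=float):
        c = int(round(tp * fs))
        lo, hi = c - half, c + half + 1
        s0 = max(0, -lo)
        s1 = len(tpl) - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if lo < hi:
            x[lo:hi] += amplitude * tpl[s0:s1]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + noise_sd * rng.standard_normal(n)
    return np.arange(n) / fs, x


def scr_kernel(t: np.ndarray, tau_rise: float = 1.0,
               tau_decay: float = 4.0) -> np.ndarray:
    """Bi-exponential skin-conductance-response kernel, unit peak."""
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0,
                 np.exp(-np.maximum(t, 0) / tau_decay)
                 - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    tpk = np.log(tau_decay / tau_rise) * tau_rise * tau_decay \
        / (tau_decay - tau_rise)
    peak = np.exp(-tpk / tau_decay) - np.exp(-tpk / tau_rise)
    return k / peak


def render_eda(pulse_times: np.ndarray, pulse_amps: np.ndarray,
               tonic_times: np.ndarray, tonic_values: np.ndarray,
               duration: float, fs: float = 16.0,
               tau_rise: float = 1.0, tau_decay: float = 4.0,
               noise_sd: float = 0.0,
               artifacts: list[tuple[float, float]] | None = None,
               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render EDA: tonic + sum of amplitude-scaled SCR kernels (+ noise).

    ``artifacts`` is an optional list of (time_s, step_uS) instantaneous
    steps injected after rendering, for artifact-removal tests.
    Raises on negative pulse amplitudes.
    """
    if fs < 2:
        raise ValueError("fs must be >= 2 Hz for EDA rendering")
    pulse_amps = np.asarray(pulse_amps, dtype=float)
    if np.any(pulse_amps < 0):
        raise ValueError("pulse amplitudes must be non-negative")
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    x = np.interp(t, tonic_times, tonic_values) if len(tonic_times) \
        else np.zeros(n)
    support = int(np.ceil((tau_decay * 8) * fs))
    ker = scr_kernel(np.arange(support) / fs, tau_rise, tau_decay)
    for tp, a in zip(np.asarray(pulse_times, dtype=float), pulse_amps):
        c = int(round(tp * fs))
        hi = min(c + support, n)
        if c < n:
            x[c:hi] += a * ker[:hi - c]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + noise_sd * rng.standard_normal(n)
    if artifacts:
        for at, step in artifacts:
            x[t >= at] += step
    return t, x
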