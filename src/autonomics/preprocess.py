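"""Waveform preprocessing: ECG R-peak detection and EDA conditioning.

R peaks are extracted with the Pan-Tompkins algorithm (band-pass,
derivative, squaring, moving-window integration, adaptive dual thresholds
with search-back), then refined to the local waveform maximum.

EDA preprocessing follows the standard two steps: (1) artifact detection
and correction — samples whose jump or local slope exceeds configurable
thresholds are flagged and bridged by shape-preserving interpolation —
followed by zero-phase low-pass filtering at 3 Hz; (2) tonic/phasic
decomposition by a smoothed running lower-percentile baseline, with
phasic = signal - tonic clipped at zero.  Sweat-release pulses are then
local maxima of the phasic component with a prominence and separation
rule; each pulse's amplitude is its height above the preceding local
minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, signal


@dataclass
class SampledSignal:
    """Uniformly sampled waveform (mV for ECG, uS for EDA)."""

    start_time: float
    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.fs

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) / self.fs


@dataclass
class EdaDecomposition:
    tonic: SampledSignal
    phasic: SampledSignal
    artifact_mask: np.ndarray


# ---------------------------------------------------------------------------
# ECG


def detect_r_peaks(ecg: SampledSignal,
                   refine_window_s: float = 0.05) -> np.ndarray:
    """Pan-Tompkins QRS detection; returns strictly increasing peak times.

    Stages: 5-15 Hz band-pass (zero-phase Butterworth), derivative,
    squaring, 150 ms moving-window integration, adaptive signal/noise
    thresholds with 1.66*RR-missed search-back.  Detections are refined
    to the maximum of |band-passed waveform| nearby.

    A flat (or all-identical) trace yields an empty result with a warning.
    """
    if ecg.fs < 100:
        raise ValueError("R-peak detection requires fs >= 100 Hz")
    x = ecg.values
    if len(x) < int(10 * ecg.fs):
        raise ValueError("R-peak detection requires >= 10 s of signal")
    if np.ptp(x) == 0:
        warnings.warn("flat ECG signal; no peaks detected")
        return np.empty(0)
    fs = ecg.fs

    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    sq = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    # candidate local maxima of the integrated signal, >=200 ms apart
    refractory = int(round(0.2 * fs))
    cand, _ = signal.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        warnings.warn("no candidate peaks in ECG")
        return np.empty(0)

    # adaptive dual-threshold pass with search-back
    init = mwi[:int(2 * fs)]
    spki = float(np.max(init)) * 0.5 if len(init) else float(mwi[cand[0]])
    npki = float(np.mean(init)) * 0.5 if len(init) else 0.0
    thr1 = npki + 0.25 * (spki - npki)
    accepted: list[int] = []
    rr_hist: list[float] = []

    def accept(idx: int) -> None:
        nonlocal spki, thr1
        spki = 0.125 * mwi[idx] + 0.875 * spki
        thr1 = npki + 0.25 * (spki - npki)
        if accepted:
            rr_hist.append((idx - accepted[-1]) / fs)
            if len(rr_hist) > 8:
                rr_hist.pop(0)
        accepted.append(idx)

    ci = 0
    while ci < len(cand):
        idx = cand[ci]
        if mwi[idx] > thr1:
            accept(idx)
        else:
            npki = 0.125 * mwi[idx] + 0.875 * npki
            thr1 = npki + 0.25 * (spki - npki)
            # search-back when the expected beat is overdue
            if rr_hist and accepted:
                rr_avg = float(np.mean(rr_hist))
                if (idx - accepted[-1]) / fs > 1.66 * rr_avg:
                    back = [c for c in cand
                            if accepted[-1] + refractory < c <= idx
                            and mwi[c] > 0.5 * thr1]
                    if back:
                        accept(max(back, key=lambda c: mwi[c]))
        ci += 1

    if not accepted:
        warnings.warn("no peaks above threshold in ECG")
        return np.empty(0)

    # refine to local maximum of the rectified band-passed waveform
    half = int(round(refine_window_s * fs))
    rect = np.abs(bp)
    peaks = []
    for idx in accepted:
        lo = max(0, idx - half)
        hi = min(len(x), idx + half + 1)
        peaks.append(lo + int(np.argmax(rect[lo:hi])))
    peaks = np.unique(peaks)
    return ecg.start_time + peaks / fs


def match_events(truth: np.ndarray, detected: np.ndarray,
                 tol: float = 0.05):
    """Greedy one-to-one matching of detected events to ground truth.

    Returns (n_matched, sensitivity, positive_predictivity, offsets).
    """
    truth = np.asarray(truth, dtype=float)
    detected = np.asarray(detected, dtype=float)
    if len(truth) == 0 or len(detected) == 0:
        return 0, 0.0, 0.0, np.empty(0)
    used = np.zeros(len(detected), dtype=bool)
    offsets = []
    for t in truth:
        i = np.searchsorted(detected, t)
        best, best_d = -1, tol
        for j in (i - 1, i):
            if 0 <= j < len(detected) and not used[j]:
                d = abs(detected[j] - t)
                if d <= best_d:
                    best, best_d = j, d
        if best >= 0:
            used[best] = True
            offsets.append(detected[best] - t)
    n = len(offsets)
    return n, n / len(truth), n / len(detected), np.asarray(offsets)


# ---------------------------------------------------------------------------
# EDA


def clean_eda(eda: SampledSignal, jump_thresh: float = 0.5,
              slope_thresh: float = 5.0, pad_s: float = 0.5,
              cutoff_hz: float = 3.0,
              max_artifact_frac: float = 0.5) -> tuple[SampledSignal, np.ndarray]:
    """Artifact removal + zero-phase 3 Hz low-pass for EDA.

    A sample is flagged when the one-sample jump exceeds ``jump_thresh``
    (uS) or the local slope exceeds ``slope_thresh`` (uS/s); flagged spans
    (padded by ``pad_s``) are bridged with monotone piecewise-cubic
    interpolation.  The cleaned trace is then low-pass filtered with a
    zero-phase Butterworth at ``cutoff_hz`` (skipped when fs <= 2*cutoff).

    Raises when more than ``max_artifact_frac`` of samples are flagged.
    """
    if eda.fs < 2:
        raise ValueError("EDA cleaning requires fs >= 2 Hz")
    x = eda.values.copy()
    fs = eda.fs
    d = np.diff(x)
    bad = np.zeros(len(x), dtype=bool)
    hit = (np.abs(d) > jump_thresh) | (np.abs(d) * fs > slope_thresh)
    bad[:-1] |= hit
    bad[1:] |= hit
    if bad.any():
        pad = int(round(pad_s * fs))
        if pad > 0:
            bad = np.convolve(bad.astype(int), np.ones(2 * pad + 1),
                              mode="same") > 0
    if bad.mean() > max_artifact_frac:
        raise ValueError("more than half of EDA samples flagged as artifact; "
                         "recording unusable")
    if bad.any() and (~bad).sum() >= 2:
        # undo persistent level shifts (step artifacts): compare the
        # medians just after vs just before each flagged span
        k = max(2, int(round(0.5 * fs)))
        spans = _contiguous_spans(bad)
        for i0, i1 in spans:
            pre = x[max(0, i0 - k):i0]
            post = x[i1 + 1:i1 + 1 + k]
            if len(pre) >= 2 and len(post):
                # extrapolate the pre-span trend across the gap so genuine
                # signal change is not mistaken for the artifact's step
                slope = float(np.polyfit(np.arange(len(pre)), pre, 1)[0])
                expect = float(np.median(pre)) + slope * (
                    (i1 + 1 + len(post) / 2.0) - (max(0, i0 - k)
                                                  + len(pre) / 2.0))
                jump = float(np.median(post)) - expect
                if abs(jump) > jump_thresh / 2.0:
                    x[i1 + 1:] -= jump
        good = np.flatnonzero(~bad)
        interp = interpolate.PchipInterpolator(good, x[good],
                                               extrapolate=True)
        xb = np.flatnonzero(bad)
        x[xb] = interp(xb)
    if fs > 2.0 * cutoff_hz:
        sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=fs,
                            output="sos")
        x = signal.sosfiltfilt(sos, x)
    return SampledSignal(eda.start_time, fs, x), bad


def _contiguous_spans(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts, ends))


def split_tonic_phasic(eda_clean: SampledSignal,
                       percentile: float = 10.0,
                       baseline_window_s: float = 30.0,
                       smooth_window_s: float = 60.0) -> EdaDecomposition:
    """Tonic/phasic decomposition by a smoothed running-percentile baseline.

    Tonic = rolling ``percentile``-th percentile over
    ``baseline_window_s``, smoothed by a ``smooth_window_s`` moving
    average (edges handled by shrinking windows); phasic = cleaned signal
    minus tonic, clipped at zero.
    """
    x = eda_clean.values
    fs = eda_clean.fs
    n = len(x)
    wb = int(round(baseline_window_s * fs))
    if n < wb:
        raise ValueError("signal shorter than the baseline window")
    ws = max(1, int(round(smooth_window_s * fs)))
    # odd-reflection padding keeps rolling statistics unbiased on linear
    # trends right up to the edges
    npad = wb + ws
    left = 2.0 * x[0] - x[npad:0:-1]
    right = 2.0 * x[-1] - x[-2:-npad - 2:-1]
    xp = np.concatenate([left, x, right])

    def baseline(arr):
        s = pd.Series(arr)
        b = s.rolling(wb, center=True, min_periods=max(2, wb // 4)) \
            .quantile(percentile / 100.0)
        return b.rolling(ws, center=True, min_periods=1).mean().to_numpy()

    tonic_p = baseline(xp)
    # bias correction: a lower-percentile baseline undershoots on ramps by
    # a constant; the floor of the residual recovers that offset
    tonic_p = tonic_p + baseline(xp - tonic_p)
    tonic = tonic_p[npad:npad + n]
    phasic = np.clip(x - tonic, 0.0, None)
    return EdaDecomposition(
        tonic=SampledSignal(eda_clean.start_time, fs, tonic),
        phasic=SampledSignal(eda_clean.start_time, fs, phasic),
        artifact_mask=np.zeros(n, dtype=bool),
    )


def extract_eda_pulses(phasic: SampledSignal,
                       prominence: float = 0.01,
                       min_separation_s: float = 1.0):
    """Sweat-release pulses from phasic EDA.

    Local maxima with prominence >= ``prominence`` uS and at least
    ``min_separation_s`` apart; two true pulses closer than the
    separation merge into one detection.  Amplitude = peak value minus
    the preceding local minimum (the peak's left base).  The reported
    pulse time is the *onset* of the rise — the last sample before the
    peak at which the signal still sits within 5% of the rise above its
    left base — since sweat release precedes the conductance peak by the
    rise time of the response.  Returns (times, amplitudes).
    """
    x = phasic.values
    if np.any(x < -1e-9):
        raise ValueError("phasic signal must be non-negative")
    fs = phasic.fs
    distance = max(1, int(round(min_separation_s * fs)))
    peaks, props = signal.find_peaks(x, prominence=prominence,
                                     distance=distance)
    if len(peaks) == 0:
        return np.empty(0), np.empty(0)
    left_bases = props["left_bases"]
    amps = np.empty(len(peaks))
    onsets = np.empty(len(peaks), dtype=int)
    for i, (pk, lb) in enumerate(zip(peaks, left_bases)):
        # preceding local minimum: bounded by the previous peak so pulses
        # riding another pulse's decay keep their own valley
        lo = max(lb, peaks[i - 1]) if i > 0 else lb
        seg = x[lo:pk + 1]
        base_idx = lo + int(np.argmin(seg))
        base = x[base_idx]
        amps[i] = x[pk] - base
        thresh = base + 0.05 * amps[i]
        below = np.flatnonzero(x[base_idx:pk + 1] <= thresh)
        onsets[i] = base_idx + (below[-1] if len(below) else 0)
    times = phasic.start_time + onsets / fs
    keep = amps > 0
    times, amps = times[keep], amps[keep]
    # separation rule can leave onsets tied/out of order; enforce strict order
    order = np.argsort(times, kind="stable")
    times, amps = times[order], amps[order]
    good = np.concatenate([[True], np.diff(times) > 0])
    return times[good], amps[good]
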