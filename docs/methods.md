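# Methods

This note documents the models, the defaults and why they were chosen,
what the synthetic generator does and does not emulate, and the numerical
decisions a maintainer would want to know. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Interval model

Inter-event intervals (R-R from ECG; inter-pulse in phasic EDA) are
inverse Gaussian, the first-passage-time law of a drifting integrator and
hence a physiologically motivated choice for pacemaker and sudomotor
dynamics:

    f(x | mu, lambda) = sqrt(lambda / (2 pi x^3))
                        exp(-lambda (x - mu)^2 / (2 mu^2 x)),  x > 0

with mean mu and shape lambda (variance mu^3/lambda). History dependence
enters through the mean: mu_j = theta0 + sum_{i=1..p} theta_i x_{j-i},
an autoregression on the p most recent intervals, which captures
autonomic influences persisting over seconds to minutes.

**Local likelihood.** The session is cut into non-overlapping windows of
length `W_fit`; within each window the likelihood of the intervals that
*end* there (each paired with its own p preceding intervals as history)
is maximized over (theta, log lambda) by L-BFGS-B, initialized by moment
matching (theta0 = window mean interval, lambda = mean^3/variance).
Parameters are held constant across the window's update grid. Estimates
begin only after the first full window: that stretch of data is consumed
fitting, so every index is undefined there and the classifier drops
feature rows whose lag windows reach into it.

Defaults: `delta` (update grid) 0.25 s as the "instantaneous" grid
(pipeline runs use 1 s — indices are later aggregated over >= 2 s
windows, so the finer grid adds cost but no information; this is the
package's own scaling choice); `W_fit` 60 s for RR. For EDA inter-pulse
intervals the default window is 300 s: at deep-sedation pulse rates
(~2/min) a 60 s window holds fewer than p+2 pulses and cannot be fitted.
Window length and AR order are per-recording hyperparameters; screening
(`screen_hyperparams`) fits every (p, W_fit) combination and keeps the
minimum KS statistic, breaking ties toward the smaller model.

Numerical guards: lambda is capped at 1e8 (near-constant intervals would
send it to infinity; the cap leaves a ~0.007 bpm floor on sigmaHR);
windows with fewer than p+2 intervals, or where the optimizer fails, are
flagged non-converged and masked rather than fatal; a candidate step
producing a non-positive mu anywhere returns a penalty so the line
search retreats. The final partial interval of each window is ignored by
default; a right-censored survival term is available (`censor_last`) but
off, since at desk scale the effect is one interval in hundreds.

**Goodness of fit.** By time rescaling, intervals pushed through the
fitted CDF are iid Uniform(0,1) under a correct model. The KS statistic
of the transforms is compared against the asymptotic 95% band
1.36/sqrt(n). The suite verifies ~5% false-alarm rate under the true
model and ~100% rejection when the mean is doubled.

## Amplitude model

EDA pulse amplitudes follow a_j ~ N(alpha0 + sum_{i=1..q} alpha_i a_{j-i},
sigma^2), fitted per window by conditional maximum likelihood (OLS on
lagged amplitudes; sigma^2 = RSS/n). With q = 0 this reduces to the
window mean and ML variance. Default q = 1.

## The 15 indices

HRV (10): muRR, sigmaRR = sqrt(mu^3/lambda), muHR and sigmaHR from the
exact reciprocal-IG moments E[1/X] = 1/mu + 1/lambda and
Var(1/X) = 1/(mu lambda) + 2/lambda^2 (chosen over the delta method
because the closed form exists and is testable by Monte Carlo — the
suite checks 0.2% agreement at 1e6 draws); LF, HF, LF/HF, LFnu, HFnu,
total power from the AR interval spectrum

    S(f) = sigma2 * ds / |1 - sum_i theta_i exp(-i 2 pi f i ds)|^2

with ds the instantaneous mean interval (the standard convention of
treating the interval series as sampled at its own mean rate) and
sigma2 = mu^3/lambda. Band powers are computed by 48-node Gauss-Legendre
quadrature per band, vectorized across the whole update grid; for these
smooth rational spectra that is accurate to ~1e-7 relative (checked
against a 1e4-point trapezoid) at a tiny fraction of the cost of adaptive
quadrature per grid point. Normalization: LFnu = LF/(LF+HF),
HFnu = HF/(LF+HF); total power integrates 0.04–0.4 Hz. Both are stated
conventions — the normalization denominator and total-power band are not
uniquely defined by the two bands alone; the alternative (0 to the
effective Nyquist) is a one-line change in `indices.py`.

EDA (5): tonic EDA (resampled to the grid), muPR and sigmaPR (the
reciprocal-IG moments of the inter-pulse model, in pulses/min), mu_amp
(the AR-predicted instantaneous mean amplitude) and sigma_amp.

Update times where a model is non-converged, the AR polynomial unstable,
or a denominator vanishes (HF = 0 for LF/HF) are masked, not zeroed.

## Rate-vs-amplitude correlation

Three stages on each index pair ((muPR, mu_amp) and (sigmaPR, sigma_amp)):
median within non-overlapping 20 s bins; moving average over 3 min
(centered — the smoothing alignment is a choice, documented here, since
either centered or trailing is defensible); Pearson r over 10 min
windows, trailing, emitted at each 20 s step. Incomplete or constant
windows are masked rather than partially computed, so the first valid
correlation appears no earlier than one correlation window into the
series. Note the effective sample size inside a 10-min window of 3-min
smoothed data is only ~3, so even independent inputs show |r| around
0.3 on average — the suite quantifies this null by simulation; observed
correlations should be read against it.

## Classification framework

Behavioral state is the regression target (ground truth by convention,
not by claim of infallibility); the indices are features. Windows of w
seconds are labeled by their midpoint (so windows straddling LOC/ROC get
a deterministic label): Q1 labels 1 inside [LOC, ROC); Q2/Q3 use t
minutes around LOC/ROC with 1 after the transition (for Q3, 1 =
conscious); Q4 uses the two baseline stages with post = 1. Each index
contributes its windowed mean or median plus M = h/w lagged copies.
Features are z-scored within subject over the question's included
windows (the alternative — z-scoring over the whole session — is
available by flag); constant features become zeros; windows where an
index is entirely masked contribute 0 after standardization.

The model is L1-penalized logistic regression (scikit-learn liblinear
backend). For each held-out subject, the penalty is selected on the
remaining subjects by 5-fold stratified cross-validation minimizing
deviance with the one-standard-error rule (strongest penalty within one
SE of the best). Held-out probabilities are pooled across subjects into
a single AUC (Mann-Whitney, ties half); per-subject AUCs are also
reported. The default penalty grid is logspace(-2.5, -0.5, 8): on
z-scored features the one-SE rule lands at strong penalties, and weaker
ones only slow the solver without changing selections; the grid is a
parameter. liblinear runs with fixed random_state, tol 1e-4, 500
iterations, making the whole procedure deterministic given the data.

AUC differences between the multimodal model and each ablation
(HRV-only; EDA-only; EDA without amplitude, i.e. tonic + muPR + sigmaPR)
get 95% CIs from a paired bootstrap that resamples *subjects* with
replacement (1000 draws), respecting the strong within-subject
correlation of windows; a CI excluding zero is flagged significant.

Leakage is guarded by construction (training never sees the held-out
subject's rows, including in inner CV) and by test: duplicating a
held-out subject's rows with shuffled labels must not change that
subject's predictions.

## Synthetic sessions

The generator emulates the study design the analysis targets: 9
subjects; ten 15-minute infusion stages targeting 0, 1, 2, 3, 4, 5,
3.75, 2.5, 1.25, 0 mg/kg/hr; LOC at minute 40 and ROC at minute 130 of a
150-minute session (a scaled-down three-hour protocol; all configurable).
Two autonomic regimes are blended: the unconscious weight is the product
of logistic gates opening at LOC and closing at ROC (half-width 120 s),
shifted per subject by an autonomic lead/lag drawn Uniform(-180, +180) s
— emulating the clinical observation that autonomic shifts precede or
trail behavioral transitions — and modulated by the normalized stage
target (0.7 + 0.3 * depth), so deeper infusion stages sit closer to the
fully unconscious regime. An `effect_scale` knob scales the regime
separation for power/null studies.

Default regime magnitudes are package constants, not measured values,
chosen to match the qualitative pharmacology (myocardial depression;
raised sweating thresholds): mean RR 0.85 -> 1.00 s, RR shape 900 ->
2500 s, EDA pulse rate ~8/min -> ~2/min, mean pulse amplitude 0.5 ->
0.25 uS, tonic 6 -> 4 uS. Amplitudes are clamped at a 0.01 uS floor
rather than rejection-sampled (the truncation bias is negligible at the
default noise level). Tonic EDA adds a slow sinusoid and smoothed noise
to the blended level.

Waveform renderers exist to exercise preprocessing, not to imitate
morphology: the ECG is a stereotyped QRS-like wavelet at each R time (no
P/T waves), and EDA is tonic plus amplitude-scaled bi-exponential
skin-conductance-response kernels (rise 1 s, decay 4 s, unit peak), with
optional noise and injectable step artifacts.

**What passing tests show — and don't.** The generator draws from the
same model family the analysis fits, so parameter-recovery and
classification results certify correctness of the estimation and
decision machinery, not robustness to model misspecification, ectopic
beats, movement artifacts beyond steps, electrode drift, drug
co-administration (e.g. vasopressors), or real inter-subject physiology.
The near-perfect synthetic AUCs reflect the generator's deliberately
strong regime separation and should not be read as expected performance
on recordings.

## Preprocessing

R peaks: Pan-Tompkins (5–15 Hz zero-phase band-pass, derivative,
squaring, 150 ms moving-window integration, adaptive signal/noise
thresholds with 1.66*RR search-back), refined to the local maximum of
the rectified band-passed waveform. Zero-phase filtering avoids timing
bias in latencies.

EDA: samples are flagged as artifact when the per-sample jump exceeds
0.5 uS or the local slope exceeds 5 uS/s (physiological responses stay
near 2 uS/s even for large pulses); persistent level shifts across a
flagged span are undone by comparing the post-span median against the
pre-span trend extrapolated over the gap; flagged spans are bridged by
monotone cubic interpolation; then a zero-phase 3 Hz low-pass (skipped
when the sampling rate cannot support it). A recording with more than
half its samples flagged is rejected. Cleaning is idempotent.

Tonic/phasic split: rolling 10th percentile over 30 s, smoothed 60 s,
with two refinements — odd-reflection padding so rolling statistics stay
unbiased on trends at the edges, and a residual-floor correction that
removes the constant undershoot a lower-percentile baseline exhibits on
ramps. The percentile baseline was chosen over deconvolution for
determinism and speed and is interchangeable behind the interface.
Phasic = signal - tonic, clipped at zero.

Pulse extraction: local maxima of phasic with prominence >= 0.01 uS and
>= 1 s separation (closer true pulses merge into one detection — a
documented limit, not a bug); amplitude = peak minus the preceding local
minimum (bounded by the previous peak); the reported time is the *onset*
of the rise (last sample within 5% of the rise above base), since sweat
release precedes the conductance peak by the kernel rise time.

Assumed sampling rates for rendered data are 250 Hz (ECG) and 16 Hz
(EDA); both are package assumptions, not measured properties.

## Problem sizes and determinism

End-to-end runs use 9 subjects x 150 min, RR AR order p = 1, index grid
1 s, and the fixed classifier configuration w = 20 s / median / h = 120 s
(the full hyperparameter sweep in `run_question` is exercised on small
grids in tests). All randomness flows from explicit seeds; reruns with an
identical config are bit-identical, and every CSV artifact carries a
config hash.

## Known limitations

- The IG model family is shared between generator and estimator; no
  misspecification stress tests beyond the mean-doubling GoF check.
- No ectopy handling or beat classification on the ECG path; no EDA
  deconvolution option.
- The spectrum's interval-sampling convention makes band edges drift
  with the instantaneous mean interval; standard, but worth remembering
  when comparing across heart-rate regimes.
- Continuous-time conditional intensity between events and state-space
  (Kalman) parameter evolution are out of scope; parameters are
  piecewise constant across fitting windows.
- Q1's class imbalance (unconscious windows outnumber conscious ones at
  the default design) is left unadjusted.
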