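"""Inverse-Gaussian engine: density, local-likelihood fits, GoF, screening."""

import numpy as np
import pytest
from scipy import integrate, stats

from autonomics.point_process import (IGModelConfig, LAMBDA_CAP,
                                      fit_amp_local, fit_ig_local, ig_cdf,
                                      ig_logpdf, pit_ks_gof, pit_ks_uniform,
                                      screen_hyperparams)
from autonomics.synthetic import (RegimeParams, simulate_amplitudes,
                                  simulate_ig_train)


class TestLogPdf:
    def test_value_at_mode_point(self):
        # at x = mu the exponent vanishes: log f = -log(2 pi)/2 for mu=lam=1
        assert ig_logpdf(1.0, 1.0, 1.0) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_density_integrates_to_one(self):
        val, err = integrate.quad(
            lambda x: np.exp(ig_logpdf(x, 0.8, 50.0)), 1e-12, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mode_matches_closed_form(self):
        mu, lam = 1.0, 3.0
        xs = np.linspace(0.01, 3.0, 300_000)
        grid_mode = xs[np.argmax(ig_logpdf(xs, mu, lam))]
        closed = mu * (np.sqrt(1 + (1.5 * mu / lam) ** 2) - 1.5 * mu / lam)
        assert grid_mode == pytest.approx(closed, abs=1e-4)

    def test_agrees_with_scipy_parameterization(self):
        x = np.array([0.3, 0.9, 1.7])
        mu, lam = 0.9, 40.0
        expected = stats.invgauss.logpdf(x / lam, mu / lam) - np.log(lam)
        np.testing.assert_allclose(ig_logpdf(x, mu, lam), expected,
                                   rtol=1e-12)

    def test_rejects_nonpositive(self):
        for bad in [(0.0, 1, 1), (1, -1, 1), (1, 1, 0)]:
            with pytest.raises(ValueError):
                ig_logpdf(*bad)


class TestFitIGLocal:
    def test_constant_intervals_cap_lambda(self):
        ev = np.arange(0.0, 100.0, 0.8)
        traj = fit_ig_local(ev, IGModelConfig(p=0, W_fit=50.0, delta=1.0))
        k = np.flatnonzero(traj.window_converged)
        assert traj.window_params[k[0], 0] == pytest.approx(0.8, abs=1e-9)
        assert traj.window_params[k[0], -1] == LAMBDA_CAP

    def test_parameter_recovery_ar1(self):
        # theta0 = 1.0, theta1 = 0.3, lambda = 800, ~3000 events, one window
        pars = RegimeParams(mu_base=1.0 / 0.7, ar_coeffs=(0.3,),
                            lambda_shape=800.0)
        ev = simulate_ig_train(lambda t: pars, 3000 * pars.mu_base, seed=3)
        cfg = IGModelConfig(p=1, W_fit=ev[-1] - ev[0] - 1e-6, delta=10.0)
        traj = fit_ig_local(ev, cfg)
        theta0, theta1, lam = traj.window_params[0]
        assert theta0 == pytest.approx(1.0, rel=0.05)
        assert theta1 == pytest.approx(0.3, rel=0.05 / 0.3 * 1.0, abs=0.05)
        assert lam == pytest.approx(800.0, rel=0.05)

    def test_no_estimates_before_first_window(self, stationary_rr):
        ev = simulate_ig_train(lambda t: stationary_rr, 400.0, seed=6)
        traj = fit_ig_local(ev, IGModelConfig(p=1, W_fit=90.0, delta=0.5))
        early = traj.update_times < ev[0] + 90.0
        assert early.any()
        assert not traj.converged[early].any()
        assert traj.converged[~early].mean() > 0.9

    def test_grid_step_and_windowwise_constancy(self, stationary_rr):
        ev = simulate_ig_train(lambda t: stationary_rr, 400.0, seed=8)
        cfg = IGModelConfig(p=0, W_fit=100.0, delta=0.25)
        traj = fit_ig_local(ev, cfg)
        np.testing.assert_allclose(np.diff(traj.update_times), 0.25)
        # parameters piecewise constant: few unique values
        vals = traj.theta0[traj.converged]
        assert len(np.unique(vals)) <= len(traj.window_starts)

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError):
            fit_ig_local(np.array([0.0, 1.0, 2.0]),
                         IGModelConfig(p=0, W_fit=60.0, delta=1.0))

    def test_sparse_window_flagged_not_fatal(self):
        # second window holds a single interval (< p+2): flagged
        ev = np.concatenate([np.arange(0.0, 50.0, 0.5), [95.0, 104.0]])
        traj = fit_ig_local(ev, IGModelConfig(p=0, W_fit=50.0, delta=1.0))
        assert traj.window_converged[0]
        assert not traj.window_converged[1]


class TestFitAmpLocal:
    def test_constant_amplitudes(self):
        t = np.arange(0.0, 300.0, 2.0)
        a = np.full(len(t), 0.42)
        traj = fit_amp_local(t, a, q=0, W_fit=290.0)
        k = np.flatnonzero(traj.window_converged)[0]
        assert traj.window_params[k, 0] == pytest.approx(0.42)
        assert traj.window_params[k, -1] == pytest.approx(0.0, abs=1e-12)

    def test_q0_closed_form_ml(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 200.0, 1.0)
        a = 0.5 + 0.1 * rng.standard_normal(len(t))
        traj = fit_amp_local(t, a, q=0, W_fit=199.0)
        k = np.flatnonzero(traj.window_converged)[0]
        inside = a[t < 199.0]      # the window is half-open [0, 199)
        assert traj.window_params[k, 0] == pytest.approx(inside.mean(),
                                                         abs=1e-9)
        assert traj.window_params[k, -1] == pytest.approx(
            inside.var(), abs=1e-9)  # ML divisor n

    def test_ar1_recovery(self):
        pars = RegimeParams(mu_base=1.0, amp_mean=0.3 / 0.5, amp_ar=(0.5,),
                            amp_sd=0.05)
        t = np.arange(0.0, 2000.0, 1.0)
        a = simulate_amplitudes(lambda t_: pars, t, seed=4, floor=1e-4)
        traj = fit_amp_local(t, a, q=1, W_fit=1999.0)
        k = np.flatnonzero(traj.window_converged)[0]
        a0, a1, s2 = traj.window_params[k]
        assert a0 == pytest.approx(0.3, rel=0.10)
        assert a1 == pytest.approx(0.5, rel=0.10)
        assert s2 == pytest.approx(0.05 ** 2, rel=0.10)


class TestGof:
    def test_pit_values_in_unit_interval(self, stationary_rr):
        ev = simulate_ig_train(lambda t: stationary_rr, 500.0, seed=9)
        traj = fit_ig_local(ev, IGModelConfig(p=0, W_fit=100.0, delta=1.0))
        rep = pit_ks_gof(ev, traj)
        assert np.all((rep.pit_values >= 0) & (rep.pit_values <= 1))
        assert rep.passed == (rep.ks_stat <= rep.ks_band)

    def test_well_specified_model_passes(self, stationary_rr):
        ev = simulate_ig_train(lambda t: stationary_rr, 2000.0, seed=10)
        traj = fit_ig_local(ev, IGModelConfig(p=1, W_fit=500.0, delta=1.0))
        assert pit_ks_gof(ev, traj).passed

    def test_calibration_under_true_model(self):
        # PIT through the generating model's own CDF: ~5% rejections
        rng = np.random.default_rng(11)
        rej = 0
        for _ in range(200):
            x = rng.wald(1.0, 800.0, size=2000)
            ks, band = pit_ks_uniform(ig_cdf(x, 1.0, 800.0))
            rej += ks > band
        assert 0.02 <= rej / 200 <= 0.08

    def test_misspecified_mean_rejected(self):
        rng = np.random.default_rng(12)
        rej = 0
        for _ in range(100):
            x = rng.wald(1.0, 800.0, size=2000)
            ks, band = pit_ks_uniform(ig_cdf(x, 2.0, 800.0))
            rej += ks > band
        assert rej == 100

    def test_too_few_events_raise(self):
        ev = np.arange(0.0, 70.0, 10.0)
        traj = fit_ig_local(np.arange(0.0, 70.0, 0.5),
                            IGModelConfig(p=0, W_fit=30.0, delta=1.0))
        with pytest.raises(ValueError):
            pit_ks_gof(ev, traj)


class TestScreening:
    def test_single_element_grid_returned(self, stationary_rr):
        ev = simulate_ig_train(lambda t: stationary_rr, 500.0, seed=13)
        cfg = screen_hyperparams(ev, [1], [120.0], delta=1.0)
        assert cfg.p == 1 and cfg.W_fit == 120.0

    def test_deterministic(self, stationary_rr):
        ev = simulate_ig_train(lambda t: stationary_rr, 800.0, seed=14)
        a = screen_hyperparams(ev, [0, 1], [120.0, 200.0], delta=1.0)
        b = screen_hyperparams(ev, [0, 1], [120.0, 200.0], delta=1.0)
        assert (a.p, a.W_fit) == (b.p, b.W_fit)

    def test_selects_history_for_ar2_data(self):
        hits = 0
        for seed in range(20):
            pars = RegimeParams(mu_base=1.0 / (1 - 0.65),
                                ar_coeffs=(0.4, 0.25), lambda_shape=2000.0)
            ev = simulate_ig_train(lambda t: pars, 3000.0, seed=100 + seed)
            cfg = screen_hyperparams(ev, [0, 1, 2], [1000.0], delta=10.0)
            hits += cfg.p >= 1
        assert hits >= 16  # >= 80% of seeds

    def test_empty_grid_raises(self, stationary_rr):
        ev = simulate_ig_train(lambda t: stationary_rr, 300.0, seed=15)
        with pytest.raises(ValueError):
            screen_hyperparams(ev, [], [60.0])


def test_optimum_beats_truth(stationary_rr):
    """The fitted likelihood must be at least the truth's likelihood."""
    ev = simulate_ig_train(lambda t: stationary_rr, 2000.0, seed=16)
    x = np.diff(ev)
    traj = fit_ig_local(ev, IGModelConfig(
        p=0, W_fit=ev[-1] - ev[0] - 1e-9, delta=10.0))
    th0, lam = traj.window_params[0]
    ll_fit = ig_logpdf(x, th0, lam).sum()
    ll_true = ig_logpdf(x, 1.0, 1000.0).sum()
    assert ll_fit >= ll_true - 1e-6
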