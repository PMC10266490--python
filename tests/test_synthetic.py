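"""Simulation scenarios: Morlet perturbations, oscillators, uniform SVAR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pericausal as pc


class TestMorlet:
    def test_center_value_and_length(self):
        prof = pc.PerturbationProfile(amplitude=4.0, alpha=2 / 25,
                                      duration=101)
        wave = pc.morlet_innovation_mean(prof)
        assert len(wave) == 101
        assert wave[50] == pytest.approx(4.0)

    def test_zero_amplitude(self):
        wave = pc.morlet_innovation_mean(pc.PerturbationProfile(amplitude=0.0))
        np.testing.assert_array_equal(wave, 0.0)

    @given(H=st.floats(-5, 5), alpha=st.floats(0.01, 1.0),
           duration=st.sampled_from([5, 21, 101]))
    @settings(max_examples=30, deadline=None)
    def test_even_symmetry(self, H, alpha, duration):
        wave = pc.morlet_innovation_mean(
            pc.PerturbationProfile(amplitude=H, alpha=alpha,
                                   duration=duration))
        np.testing.assert_allclose(wave, wave[::-1], atol=1e-12)

    def test_even_duration_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            pc.PerturbationProfile(duration=100)


class TestPerturbationScenario:
    def test_zero_amplitude_equals_stationary_run(self):
        rec0, centers = pc.simulate_perturbation_scenario(
            profile=pc.PerturbationProfile(amplitude=0.0), n_events=5,
            seed=4, burn_in=100)
        model = pc.perturbation_model()
        ens = pc.simulate_svar(model, 1, rec0.shape[0], burn_in=100, seed=4)
        np.testing.assert_array_equal(rec0, ens.data[0])

    def test_no_events_mean_is_zero(self):
        rec, centers = pc.simulate_perturbation_scenario(
            n_events=0, seed=6, burn_in=200)
        assert centers.size == 0
        assert abs(rec.mean()) < 3 * rec.std() / np.sqrt(rec.shape[0] / 20)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pc.simulate_perturbation_scenario(n_events=3,
                                              inter_event_spacing=50)

    def test_innovation_mean_recovered_at_events(self):
        """Ground-truth-aligned estimation recovers the Morlet profile as
        the per-time innovation mean of the cause channel."""
        rec, centers = pc.simulate_perturbation_scenario(n_events=400,
                                                         seed=8)
        gt = pc.ground_truth_ensemble(rec, centers)
        mom = pc.compute_moments(gt, 4)
        fit = pc.fit_svar(mom)
        prof = pc.morlet_innovation_mean(pc.PerturbationProfile())
        k_true = np.zeros(mom.n_t)
        half = 50
        for i, tp in enumerate(mom.peri_times):
            if -half <= tp <= half:
                k_true[i] = prof[tp + half]
        # intercept standard error: sqrt(s2 (1/n + mu' S^-1 mu / (n-1)))
        p = 4
        cols = np.arange(2, 2 + 2 * p)
        se = np.empty(mom.n_t)
        for i in range(mom.n_t):
            S = mom.cov[i][np.ix_(cols, cols)]
            mu = mom.mean[i, cols]
            se[i] = np.sqrt(fit.s2[i] * (1.0 / mom.n_trials
                                         + mu @ np.linalg.solve(S, mu)
                                         / (mom.n_trials - 1)))
        z = np.abs(fit.k2 - k_true) / se
        assert np.mean(z) < 1.5
        assert np.max(z) < 5.0


class TestOscillators:
    def test_zero_input_stays_at_rest(self):
        params = pc.OscillatorParams(coupling=0.0, var_nx=0.0, var_ny=0.0)
        ens = pc.simulate_coupled_oscillators(
            params, n_trials=3, n_samples=50, burn_in=10, seed=0,
            initial_state=np.zeros((3, 4)))
        np.testing.assert_array_equal(ens.data, 0.0)

    def test_explosion_raises(self):
        # Euler is unstable for omega > 2: trajectories must be refused
        params = pc.OscillatorParams(omega_y=3.0, var_nx=0.0, var_ny=0.0)
        with pytest.raises(FloatingPointError, match="max"):
            pc.simulate_coupled_oscillators(
                params, n_trials=2, n_samples=2000, burn_in=0, seed=1,
                initial_state=np.ones((2, 4)))

    def test_driven_oscillation_near_cause_period(self):
        """After burn-in, y inherits the slow period of x (~200 samples):
        the periodogram peak must fall in the bin containing 1/200."""
        ens = pc.simulate_coupled_oscillators(pc.OscillatorParams(),
                                              n_trials=50, n_samples=500,
                                              burn_in=500, seed=3)
        from scipy.signal import periodogram
        f, P = periodogram(ens.data[:, :, 1], fs=1.0, axis=1)
        peak = f[np.argmax(P.mean(axis=0))]
        assert abs(peak - 1.0 / 200.0) <= f[1]   # one frequency bin

    def test_svar2_rewriting_is_exact(self):
        """The Euler scheme is a linear 2-step recursion: feeding the same
        noise draws through the SVAR(2) rewriting reproduces the
        trajectories bit for bit."""
        params = pc.OscillatorParams()
        n_trials, total = 4, 60
        rng = np.random.default_rng(12)
        noise = np.empty((n_trials, total, 2))
        noise[:, :, 0] = np.sqrt(params.var_nx) * rng.standard_normal(
            (n_trials, total))
        noise[:, :, 1] = np.sqrt(params.var_ny) * rng.standard_normal(
            (n_trials, total))
        init = rng.standard_normal((n_trials, 4))
        osc = pc.simulate_coupled_oscillators(
            params, n_trials=n_trials, n_samples=total, burn_in=0,
            noise=noise, initial_state=init)
        model = pc.oscillator_svar2_model(params)
        # first two samples: x0, x1 = x0 + v0; innovation at time t is the
        # acceleration noise injected two Euler steps earlier
        initial = np.zeros((n_trials, 2, 2))
        initial[:, 0, 0] = init[:, 0]
        initial[:, 1, 0] = init[:, 0] + init[:, 1]
        initial[:, 0, 1] = init[:, 2]
        initial[:, 1, 1] = init[:, 2] + init[:, 3]
        eta = np.zeros((n_trials, total, 2))
        eta[:, 2:, :] = noise[:, :-2, :]
        svar = pc.simulate_svar(model, n_trials, total, burn_in=0,
                                innovations=eta, initial_values=initial)
        np.testing.assert_allclose(svar.data, osc.data, rtol=0, atol=1e-10)

    def test_noise_schedule(self):
        params = pc.OscillatorParams()
        same = pc.apply_noise_schedule(params, (10, 20), 1.0, n_samples=50)
        np.testing.assert_array_equal(same.noise_schedule, 1.0)
        down = pc.apply_noise_schedule(params, (10, 20), 0.1, n_samples=50)
        assert np.all(down.noise_schedule[10:20] == 0.1)
        assert np.all(down.noise_schedule[:10] == 1.0)
        with pytest.raises(ValueError):
            pc.apply_noise_schedule(params, (30, 20), 0.5, n_samples=50)

    def test_noise_change_barely_alters_signal_amplitude(self):
        """The transient noise reduction changes the variance of x by
        less than 5%: the oscillation amplitude dominates the noise."""
        params = pc.OscillatorParams()
        ctrl = pc.simulate_coupled_oscillators(params, n_trials=100,
                                               n_samples=500, seed=21)
        red = pc.simulate_coupled_oscillators(
            pc.apply_noise_schedule(params, (200, 300), 0.1, n_samples=500),
            n_trials=100, n_samples=500, seed=21)
        win = slice(200, 300)
        v0 = ctrl.data[:, win, 0].var()
        v1 = red.data[:, win, 0].var()
        assert abs(v1 - v0) / v0 < 0.05


class TestUniformSVAR1:
    def test_stationarity_guard(self):
        with pytest.raises(ValueError):
            pc.generate_uniform_svar1((1.2, 0.5, 0.0, 0.3), n_trials=10)

    def test_selection_recoverability(self):
        """Regression of X1_t on both lag-1 values: selecting trials on
        the *cause* at t'=0 leaves the coupling slope unbiased, selecting
        on the *effect* biases it."""
        coeffs = (0.5, 1.0, 0.0, 0.4)
        ens = pc.generate_uniform_svar1(coeffs, n_trials=20000, seed=14)

        def slope_and_se(e):
            m = pc.compute_moments(e, 1)
            fit = pc.fit_svar(m)
            se = pc.estimation.coefficient_standard_errors(m, 1)
            i = m.row(0)
            return fit.b[i, 0], se[i, 1]

        b_pop, _ = slope_and_se(ens)
        assert abs(b_pop - coeffs[1]) < 0.02

        cause = pc.single_time_selection(ens, channel=2, d0=1.0)
        b_c, se_c = slope_and_se(cause)
        assert abs(b_c - b_pop) < 3 * se_c

        effect = pc.single_time_selection(ens, channel=1, d0=1.0)
        b_e, se_e = slope_and_se(effect)
        assert abs(b_e - b_pop) > 3 * se_e

    def test_vacuous_selection_keeps_everything(self):
        ens = pc.generate_uniform_svar1((0.5, 1.0, 0.0, 0.4), n_trials=200,
                                        seed=3)
        sel = pc.single_time_selection(ens, channel=2, d0=-100.0)
        assert sel.n_trials == ens.n_trials
        np.testing.assert_array_equal(sel.data, ens.data)
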