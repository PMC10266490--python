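"""Simulation scenarios for validating the causality measures.

Three families of synthetic data are provided:

* *perturbation events*: a stationary uni-directionally coupled SVAR(4)
  whose cause-channel innovation mean is transiently driven by a
  Morlet-shaped waveform, producing oscillatory transients in both
  channels at known (ground-truth) times;
* *coupled damped oscillators*: two harmonic oscillators with
  uni-directional coupling, integrated with the Euler method (step 1
  sample), which is exactly a stationary SVAR(2) — used to study the
  behaviour of transfer entropy under strong synchrony;
* a *uniform-innovation SVAR(1)* ensemble used to visualise and test
  which conditionals survive selection (thresholding) bias.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .events import EventEnsemble
from .svar import SVARModel, simulate_svar

# SVAR(4) coefficients of the perturbation-event scenario; uni-directional
# X2 -> X1 coupling (c = 0), checked stable (companion spectral radius < 1).
PERTURBATION_A = (-0.55, -0.45, -0.55, -0.85)
PERTURBATION_B = (1.4, -0.3, 1.5, 1.7)
PERTURBATION_C = (0.0, 0.0, 0.0, 0.0)
PERTURBATION_D = (0.9, -0.25, 0.0, 0.25)


def perturbation_model() -> SVARModel:
    """The stationary SVAR(4) of the perturbation-event scenario with
    zero-mean, unit-variance innovations."""
    return SVARModel.stationary(PERTURBATION_A, PERTURBATION_B,
                                PERTURBATION_C, PERTURBATION_D)


@dataclass
class PerturbationProfile:
    """Morlet-shaped innovation-mean waveform k2(x) = H exp(-(a x)^2 / 2)
    cos(5 a x) on an integer grid x = -(duration-1)/2 .. +(duration-1)/2.

    ``amplitude`` H is the value at the centre (x = 0); ``alpha`` sets the
    envelope width.  Duration must be odd so the centre is a sample.
    """

    amplitude: float = 4.0
    alpha: float = 2.0 / 25.0
    duration: int = 101

    def __post_init__(self) -> None:
        if self.duration % 2 == 0:
            raise ValueError("duration must be odd (no unambiguous centre)")


def morlet_innovation_mean(profile: PerturbationProfile) -> np.ndarray:
    """Evaluate the Morlet waveform; even-symmetric, value H at x = 0."""
    half = (profile.duration - 1) // 2
    x = np.arange(-half, half + 1, dtype=float)
    ax = profile.alpha * x
    return profile.amplitude * np.exp(-(ax ** 2) / 2.0) * np.cos(5.0 * ax)


def simulate_perturbation_scenario(
        model: SVARModel | None = None,
        profile: PerturbationProfile | None = None,
        n_events: int = 500,
        inter_event_spacing: int = 260,
        seed: int = 0,
        burn_in: int = 500,
        edge_margin: int = 260) -> tuple[np.ndarray, np.ndarray]:
    """Continuous bivariate recording with Morlet perturbation events.

    The cause-channel innovation mean equals the Morlet profile around each
    event centre (centres on a regular ``inter_event_spacing`` grid) and is
    zero elsewhere.  Returns ``(recording, centers)`` where ``recording``
    has shape (N, 2) and ``centers`` are the exact ground-truth reference
    times (0-based sample indices into the recording).
    """
    model = perturbation_model() if model is None else model
    profile = PerturbationProfile() if profile is None else profile
    if not model.has_stationary_coefficients:
        raise ValueError("perturbation scenario expects a stationary base model")
    half = (profile.duration - 1) // 2
    if inter_event_spacing <= profile.duration:
        raise ValueError(
            f"inter_event_spacing {inter_event_spacing} would overlap events "
            f"of duration {profile.duration}")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")

    n_samples = 2 * edge_margin + max(n_events - 1, 0) * inter_event_spacing + 1
    total = burn_in + n_samples
    centers = edge_margin + inter_event_spacing * np.arange(n_events)

    wave = morlet_innovation_mean(profile)
    k2 = np.zeros(total)
    for c in centers:
        lo = burn_in + c - half
        k2[lo:lo + profile.duration] += wave
    full = model.resolved(total)
    full = SVARModel(order=full.order, coeff_a=full.coeff_a,
                     coeff_b=full.coeff_b, coeff_c=full.coeff_c,
                     coeff_d=full.coeff_d,
                     innov_mean_1=full.innov_mean_1,
                     innov_mean_2=full.innov_mean_2 + k2,
                     innov_var_1=full.innov_var_1,
                     innov_var_2=full.innov_var_2)
    ens = simulate_svar(full, n_trials=1, n_samples=n_samples,
                        burn_in=burn_in, seed=seed)
    return ens.data[0], centers


def ground_truth_ensemble(recording: np.ndarray, centers: np.ndarray,
                          window: tuple[int, int] = (99, 100)) -> EventEnsemble:
    """Peri-event ensemble aligned on the exact event centres."""
    from .events import extract_peri_event
    return extract_peri_event(recording, centers, window,
                              alignment="ground_truth", aligned_on=None)


@dataclass
class OscillatorParams:
    """Two damped harmonic oscillators, x driving y:

        x'' = -2 zx wx x' - wx^2 x + nx
        y'' = -2 zy wy y' - wy^2 y + c x + ny

    integrated with the Euler method at unit step.  ``noise_schedule``
    multiplies var_nx per retained sample (burn-in noise is unscaled);
    None means a constant 1.
    """

    zeta_x: float = 0.015722
    zeta_y: float = 0.2
    omega_x: float = 2.0 * np.pi / 200.0
    omega_y: float = 2.0 * np.pi / 20.0
    coupling: float = 0.098
    var_nx: float = 0.02
    var_ny: float = 0.005
    noise_schedule: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.zeta_x < 0 or self.zeta_y < 0:
            raise ValueError("damping ratios must be >= 0")
        if self.omega_x <= 0 or self.omega_y <= 0:
            raise ValueError("natural frequencies must be > 0")
        if self.var_nx < 0 or self.var_ny < 0:
            raise ValueError("noise variances must be >= 0")
        if self.noise_schedule is not None:
            self.noise_schedule = np.asarray(self.noise_schedule, dtype=float)
            if np.any(self.noise_schedule < 0):
                raise ValueError("noise schedule values must be >= 0")


def apply_noise_schedule(params: OscillatorParams, window: tuple[int, int],
                         factor: float, n_samples: int = 500
                         ) -> OscillatorParams:
    """Multiply var_nx by ``factor`` inside ``window = [start, stop)`` of
    the retained sample axis, leaving it unchanged elsewhere."""
    start, stop = window
    if not (0 <= start < stop <= n_samples):
        raise ValueError("window must satisfy 0 <= start < stop <= n_samples")
    if factor < 0:
        raise ValueError("factor must be >= 0")
    sched = (np.ones(n_samples) if params.noise_schedule is None
             else params.noise_schedule.copy())
    if len(sched) != n_samples:
        raise ValueError("existing schedule length does not match n_samples")
    sched[start:stop] *= factor
    return replace(params, noise_schedule=sched)


def simulate_coupled_oscillators(params: OscillatorParams,
                                 n_trials: int = 2000,
                                 n_samples: int = 500,
                                 burn_in: int = 500,
                                 seed: int = 0,
                                 noise: np.ndarray | None = None,
                                 initial_state: np.ndarray | None = None
                                 ) -> EventEnsemble:
    """Euler-integrated trials of the coupled oscillator pair.

    Initial positions and velocities are standard normal.  Returns an
    ensemble with channel 1 = x (cause) and channel 2 = y (effect), the
    first ``burn_in`` samples discarded.  ``noise`` (n_trials, total, 2)
    overrides the random accelerations nx, ny; ``initial_state``
    (n_trials, 4) overrides (x0, vx0, y0, vy0).
    """
    total = burn_in + n_samples
    sched = np.ones(total)
    if params.noise_schedule is not None:
        if len(params.noise_schedule) != n_samples:
            raise ValueError(
                f"noise schedule must have length n_samples={n_samples}")
        sched[burn_in:] = params.noise_schedule
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if initial_state is None:
        initial_state = rng.standard_normal((n_trials, 4))
    else:
        initial_state = np.asarray(initial_state, dtype=float)
    if noise is None:
        z = rng.standard_normal((n_trials, total, 2))
        noise = np.empty_like(z)
        noise[:, :, 0] = np.sqrt(params.var_nx * sched)[None, :] * z[:, :, 0]
        noise[:, :, 1] = np.sqrt(params.var_ny) * z[:, :, 1]
    else:
        noise = np.asarray(noise, dtype=float)
        if noise.shape != (n_trials, total, 2):
            raise ValueError(f"noise must have shape {(n_trials, total, 2)}")

    x = np.empty((n_trials, total))
    y = np.empty((n_trials, total))
    px, vx = initial_state[:, 0].copy(), initial_state[:, 1].copy()
    py, vy = initial_state[:, 2].copy(), initial_state[:, 3].copy()
    gx = 2.0 * params.zeta_x * params.omega_x
    gy = 2.0 * params.zeta_y * params.omega_y
    wx2, wy2 = params.omega_x ** 2, params.omega_y ** 2
    for t in range(total):
        x[:, t], y[:, t] = px, py
        ax = -gx * vx - wx2 * px + noise[:, t, 0]
        ay = -gy * vy - wy2 * py + params.coupling * px + noise[:, t, 1]
        px = px + vx
        py = py + vy
        vx = vx + ax
        vy = vy + ay
        if t % 100 == 0:
            peak = max(float(np.max(np.abs(px))), float(np.max(np.abs(py))))
            if not np.isfinite(peak) or peak > 1e6:
                raise FloatingPointError(
                    f"oscillator trajectories exploded at step {t} "
                    f"(max |value| = {peak:.3g})")
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    peak = max(peak, float(np.max(np.abs(y))) if y.size else 0.0)
    if not (np.isfinite(x).all() and np.isfinite(y).all()) or peak > 1e6:
        raise FloatingPointError(
            f"oscillator trajectories exploded (max |value| = {peak:.3g})")
    data = np.stack([x[:, burn_in:], y[:, burn_in:]], axis=2)
    return EventEnsemble(data=data, peri_event_time=np.arange(n_samples),
                         alignment="ground_truth", aligned_on=None)


def oscillator_svar2_model(params: OscillatorParams) -> SVARModel:
    """Exact SVAR(2) rewriting of the Euler scheme.

    Eliminating the velocities from the two-step Euler recursion gives

        x_{t+2} = (2 - 2 zx wx) x_{t+1} - (1 - 2 zx wx + wx^2) x_t + nx_t
        y_{t+2} = (2 - 2 zy wy) y_{t+1} - (1 - 2 zy wy + wy^2) y_t
                  + c x_t + ny_t

    i.e. the innovation entering the SVAR equation at time t is the random
    acceleration injected two Euler steps earlier.  Channel 1 = x,
    channel 2 = y, so the ground-truth causal direction is 1 -> 2.
    """
    gx = 2.0 * params.zeta_x * params.omega_x
    gy = 2.0 * params.zeta_y * params.omega_y
    a = (2.0 - gx, -(1.0 - gx + params.omega_x ** 2))
    d = (2.0 - gy, -(1.0 - gy + params.omega_y ** 2))
    return SVARModel.stationary(
        coeff_a=a, coeff_b=(0.0, 0.0),
        coeff_c=(0.0, params.coupling), coeff_d=d,
        innov_var_1=max(params.var_nx, np.finfo(float).tiny),
        innov_var_2=max(params.var_ny, np.finfo(float).tiny))


def generate_uniform_svar1(coefficients: tuple[float, float, float, float],
                           innovation_half_width: float = 1.0,
                           n_trials: int = 5000,
                           n_samples: int = 9,
                           seed: int = 0,
                           burn_in: int = 50) -> EventEnsemble:
    """Bivariate SVAR(1) trials with *uniform* (not Gaussian) innovations.

    ``coefficients`` are the scalars (a, b, c, d) of the two lag-1
    equations.  Innovations are Uniform(-h, +h).  The peri-event time axis
    is centred so t' = 0 falls mid-window; used to illustrate which
    regression conditionals survive threshold selection.
    """
    a, b, c, d = coefficients
    if abs(a) >= 1 or abs(d) >= 1:
        raise ValueError("need |a| < 1 and |d| < 1 for stationarity")
    model = SVARModel.stationary((a,), (b,), (c,), (d,))
    stable_total = burn_in + n_samples
    h = float(innovation_half_width)
    rng_eta = np.empty((n_trials, stable_total, 2))
    for i in range(n_trials):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        rng_eta[i] = rng.uniform(-h, h, size=(stable_total, 2))
    ens = simulate_svar(model, n_trials=n_trials, n_samples=n_samples,
                        burn_in=burn_in, seed=seed, innovations=rng_eta)
    return EventEnsemble(data=ens.data,
                         peri_event_time=np.arange(n_samples) - n_samples // 2,
                         alignment="ground_truth", aligned_on=None)
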