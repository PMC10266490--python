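"""Time-inhomogeneous bivariate SVAR(p) model.

The generative model for a pair of signals (X1, X2) is

    X1_t = a_t' Xp1_t + b_t' Xp2_t + eta1_t,   eta1_t ~ N(k1_t, s1_t)
    X2_t = c_t' Xp1_t + d_t' Xp2_t + eta2_t,   eta2_t ~ N(k2_t, s2_t)

where ``Xpk_t = [Xk_{t-1}, ..., Xk_{t-p}]`` stacks the last p samples
most-recent-first, and every parameter may depend on (peri-event) time t.
Innovations are independent across time, trials and channels — there are
no contemporaneous effects.  All coefficient vectors follow the
most-recent-first ordering throughout the package.

Besides simulation, this module provides the companion-form stability
check and an exact forward recursion for the population mean and
covariance of the stacked state, which the causality module uses to
compute closed-form measure values free of estimation noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg as _sla

from .events import EventEnsemble


def _per_time_matrix(x, p: int, name: str) -> np.ndarray:
    """Coerce a coefficient spec to shape (T, p)."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1, 1)
    elif arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.ndim != 2 or arr.shape[1] != p:
        raise ValueError(f"{name} must have {p} lag coefficients per time")
    return arr


def _per_time_vector(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a scalar or per-time vector")
    return arr


@dataclass
class SVARModel:
    """Full generative specification of a bivariate SVAR(p).

    Coefficient arrays have shape (T, p); scalar/1-D inputs are promoted
    to a single time row (a time-invariant model, broadcast on demand).
    Variances must be strictly positive.
    """

    order: int
    coeff_a: np.ndarray
    coeff_b: np.ndarray
    coeff_c: np.ndarray
    coeff_d: np.ndarray
    innov_mean_1: np.ndarray = 0.0
    innov_mean_2: np.ndarray = 0.0
    innov_var_1: np.ndarray = 1.0
    innov_var_2: np.ndarray = 1.0

    def __post_init__(self) -> None:
        p = int(self.order)
        if p < 1:
            raise ValueError("order p must be >= 1")
        self.order = p
        self.coeff_a = _per_time_matrix(self.coeff_a, p, "coeff_a")
        self.coeff_b = _per_time_matrix(self.coeff_b, p, "coeff_b")
        self.coeff_c = _per_time_matrix(self.coeff_c, p, "coeff_c")
        self.coeff_d = _per_time_matrix(self.coeff_d, p, "coeff_d")
        self.innov_mean_1 = _per_time_vector(self.innov_mean_1, "innov_mean_1")
        self.innov_mean_2 = _per_time_vector(self.innov_mean_2, "innov_mean_2")
        self.innov_var_1 = _per_time_vector(self.innov_var_1, "innov_var_1")
        self.innov_var_2 = _per_time_vector(self.innov_var_2, "innov_var_2")
        T = max(a.shape[0] for a in self._arrays())
        for name in ("coeff_a", "coeff_b", "coeff_c", "coeff_d"):
            arr = getattr(self, name)
            if arr.shape[0] == 1:
                setattr(self, name, np.broadcast_to(arr, (T, p)).copy())
            elif arr.shape[0] != T:
                raise ValueError(f"{name} has inconsistent time length")
        for name in ("innov_mean_1", "innov_mean_2", "innov_var_1", "innov_var_2"):
            arr = getattr(self, name)
            if arr.shape[0] == 1:
                setattr(self, name, np.broadcast_to(arr, (T,)).copy())
            elif arr.shape[0] != T:
                raise ValueError(f"{name} has inconsistent time length")
        if np.any(self.innov_var_1 <= 0) or np.any(self.innov_var_2 <= 0):
            raise ValueError("innovation variances must be strictly positive")

    def _arrays(self):
        return (self.coeff_a, self.coeff_b, self.coeff_c, self.coeff_d,
                self.innov_mean_1, self.innov_mean_2,
                self.innov_var_1, self.innov_var_2)

    # --- basic properties -----------------------------------------------

    @property
    def n_times(self) -> int:
        return self.coeff_a.shape[0]

    @property
    def is_time_invariant(self) -> bool:
        return all(np.all(a == a[:1]) for a in self._arrays())

    @property
    def has_stationary_coefficients(self) -> bool:
        """True when a, b, c, d (but not necessarily the innovation
        parameters) are constant in time."""
        return all(np.all(m == m[:1]) for m in
                   (self.coeff_a, self.coeff_b, self.coeff_c, self.coeff_d))

    @classmethod
    def stationary(cls, coeff_a, coeff_b, coeff_c, coeff_d,
                   innov_mean_1=0.0, innov_mean_2=0.0,
                   innov_var_1=1.0, innov_var_2=1.0) -> "SVARModel":
        """Time-invariant model from length-p coefficient vectors."""
        a = np.atleast_1d(np.asarray(coeff_a, dtype=float))
        return cls(order=a.shape[0], coeff_a=a, coeff_b=coeff_b,
                   coeff_c=coeff_c, coeff_d=coeff_d,
                   innov_mean_1=innov_mean_1, innov_mean_2=innov_mean_2,
                   innov_var_1=innov_var_1, innov_var_2=innov_var_2)

    def resolved(self, T: int) -> "SVARModel":
        """Model with per-time arrays of length exactly ``T``.

        A single-row (time-invariant) model is tiled; any other length
        mismatch is an error, since there is no unambiguous way to stretch
        a time-varying parameter profile.
        """
        if self.n_times == T:
            return self
        if self.n_times == 1 or self.is_time_invariant:
            p = self.order
            return SVARModel(
                order=p,
                coeff_a=np.broadcast_to(self.coeff_a[:1], (T, p)).copy(),
                coeff_b=np.broadcast_to(self.coeff_b[:1], (T, p)).copy(),
                coeff_c=np.broadcast_to(self.coeff_c[:1], (T, p)).copy(),
                coeff_d=np.broadcast_to(self.coeff_d[:1], (T, p)).copy(),
                innov_mean_1=np.broadcast_to(self.innov_mean_1[:1], (T,)).copy(),
                innov_mean_2=np.broadcast_to(self.innov_mean_2[:1], (T,)).copy(),
                innov_var_1=np.broadcast_to(self.innov_var_1[:1], (T,)).copy(),
                innov_var_2=np.broadcast_to(self.innov_var_2[:1], (T,)).copy(),
            )
        raise ValueError(
            f"model has {self.n_times} time steps, cannot resolve to {T}")

    # --- companion form --------------------------------------------------

    def companion(self, t: int = 0) -> np.ndarray:
        """2p x 2p companion matrix at time ``t`` for the stacked state
        z_t = [X1_t .. X1_{t-p+1}, X2_t .. X2_{t-p+1}]."""
        p = self.order
        A = np.zeros((2 * p, 2 * p))
        A[0, :p] = self.coeff_a[t]
        A[0, p:] = self.coeff_b[t]
        A[p, :p] = self.coeff_c[t]
        A[p, p:] = self.coeff_d[t]
        if p > 1:
            idx = np.arange(p - 1)
            A[1 + idx, idx] = 1.0
            A[p + 1 + idx, p + idx] = 1.0
        return A

    def innovation_mean_vector(self, t: int) -> np.ndarray:
        p = self.order
        k = np.zeros(2 * p)
        k[0] = self.innov_mean_1[t]
        k[p] = self.innov_mean_2[t]
        return k

    def innovation_cov_matrix(self, t: int) -> np.ndarray:
        p = self.order
        Q = np.zeros((2 * p, 2 * p))
        Q[0, 0] = self.innov_var_1[t]
        Q[p, p] = self.innov_var_2[t]
        return Q

    # --- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "coeff_a": self.coeff_a.tolist(),
            "coeff_b": self.coeff_b.tolist(),
            "coeff_c": self.coeff_c.tolist(),
            "coeff_d": self.coeff_d.tolist(),
            "innov_mean_1": self.innov_mean_1.tolist(),
            "innov_mean_2": self.innov_mean_2.tolist(),
            "innov_var_1": self.innov_var_1.tolist(),
            "innov_var_2": self.innov_var_2.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVARModel":
        return cls(**d)

    def save_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f)

    @classmethod
    def load_json(cls, path) -> "SVARModel":
        with open(path) as f:
            return cls.from_dict(json.load(f))

    def digest(self) -> str:
        """Short content hash used to tag simulated ensembles."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stability_check(model: SVARModel) -> tuple[bool, float]:
    """(stable, spectral radius) of the companion matrix.

    For a model with stationary coefficients a single eigen-decomposition
    is enough; otherwise the radius is the maximum over time indices.
    """
    if model.has_stationary_coefficients:
        ts: np.ndarray | range = range(1)
    else:
        ts = range(model.n_times)
    radius = max(float(np.max(np.abs(np.linalg.eigvals(model.companion(t)))))
                 for t in ts)
    return radius < 1.0, radius


def simulate_svar(model: SVARModel, n_trials: int, n_samples: int,
                  burn_in: int = 500, seed: int = 0,
                  innovations: np.ndarray | None = None,
                  initial_values: np.ndarray | None = None) -> EventEnsemble:
    """Draw ``n_trials`` independent trials of length ``n_samples``.

    The first p samples start at zero (or ``initial_values``, shape
    (n_trials, p, 2)) and ``burn_in`` leading samples are discarded so the
    initial condition is forgotten.  Per-trial generator substreams are
    spawned from ``seed`` by trial index, so trial i is reproducible in
    isolation.  ``innovations`` (shape (n_trials, total, 2)) overrides the
    internally drawn eta values — useful for exactness tests.
    """
    p = model.order
    total = n_samples + burn_in
    if total <= p:
        raise ValueError("n_samples + burn_in must exceed the model order")
    m = model.resolved(total)
    if m.has_stationary_coefficients:
        stable, radius = stability_check(m)
        if not stable:
            raise ValueError(
                f"unstable SVAR: companion spectral radius {radius:.6f} >= 1")

    if innovations is None:
        eta = np.empty((n_trials, total, 2))
        sd = np.stack([np.sqrt(m.innov_var_1), np.sqrt(m.innov_var_2)], axis=1)
        mean = np.stack([m.innov_mean_1, m.innov_mean_2], axis=1)
        for i in range(n_trials):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
            eta[i] = mean + sd * rng.standard_normal((total, 2))
    else:
        eta = np.asarray(innovations, dtype=float)
        if eta.shape != (n_trials, total, 2):
            raise ValueError(
                f"innovations must have shape {(n_trials, total, 2)}")

    x = np.zeros((n_trials, total, 2))
    if initial_values is not None:
        initial_values = np.asarray(initial_values, dtype=float)
        if initial_values.shape != (n_trials, p, 2):
            raise ValueError(
                f"initial_values must have shape {(n_trials, p, 2)}")
        x[:, :p, :] = initial_values
    a, b, c, d = m.coeff_a, m.coeff_b, m.coeff_c, m.coeff_d
    for t in range(p, total):
        past1 = x[:, t - p:t, 0][:, ::-1]
        past2 = x[:, t - p:t, 1][:, ::-1]
        x[:, t, 0] = past1 @ a[t] + past2 @ b[t] + eta[:, t, 0]
        x[:, t, 1] = past1 @ c[t] + past2 @ d[t] + eta[:, t, 1]
    if not np.isfinite(x).all():
        raise FloatingPointError("simulation produced non-finite values")
    return EventEnsemble(
        data=x[:, burn_in:, :],
        peri_event_time=np.arange(n_samples),
        alignment="ground_truth",
        aligned_on=None,
    )


@dataclass
class PopulationMoments:
    """Exact per-time mean and covariance of the stacked state
    z_t = [X1_t .. X1_{t-p+1}, X2_t .. X2_{t-p+1}]."""

    order: int
    mean: np.ndarray   # (T, 2p)
    cov: np.ndarray    # (T, 2p, 2p)

    def past_stats(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """(mean, cov) of the joint stacked past [Xp1_t, Xp2_t], which is
        exactly the state one step earlier."""
        if t < 1:
            raise ValueError("past statistics need t >= 1")
        return self.mean[t - 1], self.cov[t - 1]


def stationary_state_moments(model: SVARModel, t: int = 0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Fixed point of the state mean/covariance recursion using the
    parameters at time ``t`` (discrete Lyapunov equation for the
    covariance).  Requires a stable companion matrix."""
    A = model.companion(t)
    radius = float(np.max(np.abs(np.linalg.eigvals(A))))
    if radius >= 1.0:
        raise ValueError(
            f"no stationary moments: spectral radius {radius:.6f} >= 1")
    mu = np.linalg.solve(np.eye(A.shape[0]) - A,
                         model.innovation_mean_vector(t))
    P = _sla.solve_discrete_lyapunov(A, model.innovation_cov_matrix(t))
    return mu, 0.5 * (P + P.T)


def population_moments(model: SVARModel, init: str = "stationary"
                       ) -> PopulationMoments:
    """Propagate the exact state mean/covariance through time.

    ``init='stationary'`` starts from the fixed point of the time-0
    parameters (the model is assumed to be in its stationary regime before
    any transient perturbation); ``init='zero'`` starts from a
    deterministic zero state.
    """
    T, p = model.n_times, model.order
    mu = np.zeros((T, 2 * p))
    P = np.zeros((T, 2 * p, 2 * p))
    if init == "stationary":
        mu0, P0 = stationary_state_moments(model, 0)
    elif init == "zero":
        mu0, P0 = np.zeros(2 * p), np.zeros((2 * p, 2 * p))
    else:
        raise ValueError("init must be 'stationary' or 'zero'")
    prev_mu, prev_P = mu0, P0
    for t in range(T):
        A = model.companion(t)
        prev_mu = A @ prev_mu + model.innovation_mean_vector(t)
        prev_P = A @ prev_P @ A.T + model.innovation_cov_matrix(t)
        prev_P = 0.5 * (prev_P + prev_P.T)
        mu[t], P[t] = prev_mu, prev_P
    return PopulationMoments(order=p, mean=mu, cov=P)
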