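"""Per-peri-event-time SVAR estimation across trials.

Trials of a peri-event ensemble are treated as i.i.d. draws of the same
nonstationary process, so at each peri-event time t' the present values
and the stacked lag vectors form an ordinary cross-sectional regression
problem.  Everything downstream (coefficients, innovation parameters and
the causality measures) is a function of the per-t' first and second
sample moments of the vector

    Z_t' = [X1_t', X2_t', Xp1_t' (p lags, most recent first), Xp2_t'],

so those moments are computed once and reused (including across bootstrap
resamples and BIC candidate orders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventEnsemble

# relative tolerance for pseudo-inverse fallbacks on near-singular
# second-moment matrices (low-noise, strongly synchronized regimes)
PINV_RTOL = 1e-10


def design_tensor(ensemble: EventEnsemble, p: int) -> tuple[np.ndarray, np.ndarray]:
    """(Z, t_index): Z has shape (n_trials, n_t, 2 + 2p) with the layout
    documented in the module docstring; t_index are the positions on the
    ensemble time axis where a full lag vector exists (index >= p)."""
    X = ensemble.data
    n, T, _ = X.shape
    if T <= p:
        raise ValueError(f"window of {T} samples cannot support order {p}")
    t_idx = np.arange(p, T)
    cols = [X[:, t_idx, 0], X[:, t_idx, 1]]
    for ch in (0, 1):
        for j in range(1, p + 1):
            cols.append(X[:, t_idx - j, ch])
    return np.stack(cols, axis=2), t_idx


def moments_from_design(Z: np.ndarray, p: int, t_index: np.ndarray,
                        peri_times: np.ndarray) -> "PeriEventMoments":
    n = Z.shape[0]
    mean = Z.mean(axis=0)
    Zc = Z - mean[None]
    cov = np.einsum("itm,itn->tmn", Zc, Zc) / (n - 1)
    return PeriEventMoments(p=p, peri_times=peri_times, t_index=t_index,
                            mean=mean, cov=cov, n_trials=n)


@dataclass
class PeriEventMoments:
    """Unbiased (n-1 denominator) cross-trial moments of Z at each t'.

    Column layout of ``mean``/``cov``: 0 = X1_t', 1 = X2_t',
    2 .. 2+p = X1 lags (most recent first), 2+p .. 2+2p = X2 lags.
    """

    p: int
    peri_times: np.ndarray   # (n_t,) peri-event time values
    t_index: np.ndarray      # (n_t,) indices into the ensemble time axis
    mean: np.ndarray         # (n_t, 2 + 2p)
    cov: np.ndarray          # (n_t, 2 + 2p, 2 + 2p)
    n_trials: int

    @property
    def n_t(self) -> int:
        return len(self.peri_times)

    def present_col(self, channel: int) -> int:
        return channel - 1

    def past_slice(self, channel: int) -> slice:
        start = 2 + (channel - 1) * self.p
        return slice(start, start + self.p)

    def row(self, tprime: int) -> int:
        idx = np.nonzero(self.peri_times == tprime)[0]
        if idx.size == 0:
            raise KeyError(f"no moments at peri-event time {tprime}")
        return int(idx[0])

    # convenience block accessors (cause/effect bookkeeping lives here so
    # the causality module can stay direction-agnostic)

    def mean_past(self, channel: int) -> np.ndarray:
        return self.mean[:, self.past_slice(channel)]

    def cov_past(self, chan_i: int, chan_j: int) -> np.ndarray:
        return self.cov[:, self.past_slice(chan_i), self.past_slice(chan_j)]


def compute_moments(ensemble: EventEnsemble, p: int) -> PeriEventMoments:
    """Cross-trial moments of present values and stacked lag vectors.

    Needs at least 2p + 3 trials so the full regression (2p coefficients
    plus intercept) is generically nonsingular with a residual df >= 2.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    n_min = 2 * p + 3
    if ensemble.n_trials < n_min:
        raise ValueError(
            f"need at least {n_min} trials for order {p} "
            f"(got {ensemble.n_trials})")
    Z, t_idx = design_tensor(ensemble, p)
    return moments_from_design(Z, p, t_idx, ensemble.peri_event_time[t_idx])


def _solve_regression(S_pp: np.ndarray, s_py: np.ndarray,
                      ridge: float = 0.0) -> np.ndarray:
    """Solve the per-time normal equations for a stack of times.

    ``S_pp`` has shape (n_t, q, q), ``s_py`` (n_t, q).  Falls back to a
    pseudo-inverse (relative tolerance PINV_RTOL) for singular systems.
    """
    if ridge:
        S_pp = S_pp + ridge * np.eye(S_pp.shape[-1])[None]
    try:
        beta = np.linalg.solve(S_pp, s_py[..., None])[..., 0]
        if np.isfinite(beta).all():
            return beta
    except np.linalg.LinAlgError:
        pass
    beta = np.empty_like(s_py)
    for i in range(S_pp.shape[0]):
        beta[i] = np.linalg.pinv(S_pp[i], rcond=PINV_RTOL) @ s_py[i]
    if not np.isfinite(beta).all():
        raise np.linalg.LinAlgError(
            "singular regression beyond pseudo-inverse tolerance; "
            "consider a small ridge penalty")
    return beta


def _ols_rows(moments: PeriEventMoments, target_channel: int,
              cols: np.ndarray, ridge: float = 0.0
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(beta, intercept, unbiased residual variance) of the cross-trial
    regression of the target present value on the moment columns ``cols``
    plus an intercept, at every t'."""
    y = moments.present_col(target_channel)
    n = moments.n_trials
    S_pp = moments.cov[:, cols[:, None], cols[None, :]]
    s_py = moments.cov[:, cols, y]
    s_yy = moments.cov[:, y, y]
    beta = _solve_regression(S_pp, s_py, ridge=ridge)
    intercept = moments.mean[:, y] - np.einsum(
        "tq,tq->t", beta, moments.mean[:, cols])
    explained = np.einsum("tq,tq->t", beta, s_py)
    df = n - len(cols) - 1
    if df < 1:
        raise ValueError("not enough trials for an unbiased residual variance")
    resid_var = np.maximum(s_yy - explained, 0.0) * (n - 1) / df
    return beta, intercept, resid_var


@dataclass
class TimeVaryingFit:
    """Per-t' OLS estimates of the full bivariate SVAR: coefficient
    vectors, innovation mean (the regression intercept) and unbiased
    innovation variance for both target channels."""

    p: int
    peri_times: np.ndarray
    a: np.ndarray   # (n_t, p) X1-past -> X1
    b: np.ndarray   # (n_t, p) X2-past -> X1
    c: np.ndarray   # (n_t, p) X1-past -> X2
    d: np.ndarray   # (n_t, p) X2-past -> X2
    k1: np.ndarray
    k2: np.ndarray
    s1: np.ndarray  # innovation variance estimates, channel 1
    s2: np.ndarray
    n_trials: int = 0

    def own_cross(self, target_channel: int
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(own-past coeffs, cross-past coeffs, intercept, variance) for
        the equation of ``target_channel``."""
        if target_channel == 1:
            return self.a, self.b, self.k1, self.s1
        return self.d, self.c, self.k2, self.s2

    def row(self, tprime: int) -> int:
        idx = np.nonzero(self.peri_times == tprime)[0]
        if idx.size == 0:
            raise KeyError(f"no fit at peri-event time {tprime}")
        return int(idx[0])


@dataclass
class ReducedFit:
    """Own-past-only fit of one channel (the reduced model of Granger
    causality), re-estimated from the same data."""

    p_reduced: int
    channel: int
    peri_times: np.ndarray
    coeffs: np.ndarray
    k: np.ndarray
    s: np.ndarray


def fit_svar(moments: PeriEventMoments, ridge: float = 0.0) -> TimeVaryingFit:
    """Full-model OLS at every t' for both channels."""
    p = moments.p
    cols = np.arange(2, 2 + 2 * p)
    b1, k1, s1 = _ols_rows(moments, 1, cols, ridge)
    b2, k2, s2 = _ols_rows(moments, 2, cols, ridge)
    return TimeVaryingFit(p=p, peri_times=moments.peri_times,
                          a=b1[:, :p], b=b1[:, p:],
                          c=b2[:, :p], d=b2[:, p:],
                          k1=k1, k2=k2, s1=s1, s2=s2,
                          n_trials=moments.n_trials)


def fit_svar_at_time(moments: PeriEventMoments, tprime: int,
                     target_channel: int) -> dict:
    """Single-t' view of the full fit for one target channel."""
    fit = fit_svar(moments)
    i = fit.row(tprime)
    own, cross, k, s = fit.own_cross(target_channel)
    return {"own": own[i], "cross": cross[i],
            "innov_mean": float(k[i]), "innov_var": float(s[i])}


def fit_reduced(moments: PeriEventMoments, channel: int,
                p_reduced: int | None = None, ridge: float = 0.0) -> ReducedFit:
    """Own-past-only regression of ``channel`` (defaults to the full
    order, keeping GC comparable with TE)."""
    p = moments.p
    pr = p if p_reduced is None else int(p_reduced)
    if not (1 <= pr <= p):
        raise ValueError(f"reduced order must be in 1..{p}")
    start = 2 + (channel - 1) * p
    cols = np.arange(start, start + pr)   # most-recent-first: first pr lags
    beta, k, s = _ols_rows(moments, channel, cols, ridge)
    return ReducedFit(p_reduced=pr, channel=channel,
                      peri_times=moments.peri_times, coeffs=beta, k=k, s=s)


def fit_reduced_at_time(moments: PeriEventMoments, tprime: int,
                        channel: int, p_reduced: int | None = None) -> dict:
    red = fit_reduced(moments, channel, p_reduced)
    idx = np.nonzero(red.peri_times == tprime)[0]
    if idx.size == 0:
        raise KeyError(f"no fit at peri-event time {tprime}")
    i = int(idx[0])
    return {"coeffs": red.coeffs[i], "innov_mean": float(red.k[i]),
            "innov_var": float(red.s[i])}


@dataclass
class BICSelection:
    selected_order: int
    orders: np.ndarray
    bic: np.ndarray


def select_model_order_bic(ensemble: EventEnsemble, p_max: int,
                           orders=None) -> BICSelection:
    """Time-varying BIC over candidate orders 1..p_max.

    All candidates are scored on the identical observation set (lags
    trimmed to p_max).  The score sums, over peri-event times and both
    channels, the Gaussian log-likelihood term n * ln(ML residual
    variance), and penalises the full per-time parameter count (2p
    coefficients, intercept and variance per channel and time) times the
    log of the total scalar observation count.  Ties go to the smallest
    order.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    orders = np.arange(1, p_max + 1) if orders is None else np.asarray(orders)
    moments = compute_moments(ensemble, p_max)
    n, n_t = moments.n_trials, moments.n_t
    n_obs = n * n_t * 2
    tiny = np.finfo(float).tiny
    bic = np.empty(len(orders))
    for j, p in enumerate(orders):
        cols = np.concatenate([np.arange(2, 2 + p),
                               np.arange(2 + p_max, 2 + p_max + p)])
        ll_term = 0.0
        for ch in (1, 2):
            _, _, s = _ols_rows(moments, ch, cols)
            s_ml = np.maximum(s * (n - len(cols) - 1) / n, tiny)
            ll_term += float(n * np.log(s_ml).sum())
        n_params = n_t * 2 * (2 * p + 2)
        bic[j] = ll_term + n_params * np.log(n_obs)
    best = int(orders[int(np.argmin(bic))])
    return BICSelection(selected_order=best, orders=orders, bic=bic)


def coefficient_standard_errors(moments: PeriEventMoments,
                                target_channel: int) -> np.ndarray:
    """Asymptotic OLS standard errors of the full-model coefficient
    estimates, shape (n_t, 2p): sqrt(sigma^2 [S_pp^-1]_jj / (n-1))."""
    p = moments.p
    cols = np.arange(2, 2 + 2 * p)
    _, _, s = _ols_rows(moments, target_channel, cols)
    S_pp = moments.cov[:, cols[:, None], cols[None, :]]
    try:
        inv_diag = np.diagonal(np.linalg.inv(S_pp), axis1=1, axis2=2)
    except np.linalg.LinAlgError:
        inv_diag = np.stack([np.diag(np.linalg.pinv(S, rcond=PINV_RTOL))
                             for S in S_pp])
    return np.sqrt(np.maximum(s[:, None] * inv_diag, 0.0)
                   / (moments.n_trials - 1))


def fits_to_frame(fit: TimeVaryingFit):
    """Long-format DataFrame (t', channel, parameter, value) for export."""
    import pandas as pd
    rows = []
    for i, tp in enumerate(fit.peri_times):
        for ch, (own, cross, k, s) in (
                (1, (fit.a, fit.b, fit.k1, fit.s1)),
                (2, (fit.d, fit.c, fit.k2, fit.s2))):
            for j in range(fit.p):
                rows.append((tp, ch, f"own_lag{j + 1}", own[i, j]))
                rows.append((tp, ch, f"cross_lag{j + 1}", cross[i, j]))
            rows.append((tp, ch, "innov_mean", k[i]))
            rows.append((tp, ch, "innov_var", s[i]))
    return pd.DataFrame(rows, columns=["t_prime", "channel", "parameter",
                                       "value"])
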