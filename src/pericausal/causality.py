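"""Time-varying causal-influence measures for bivariate SVAR ensembles.

All four measures compare, at each peri-event time t', the full
conditional of the effect's present value given both stacked pasts with a
conditional in which the cause's contribution has been removed in some
way.  Under the Gaussian SVAR model each has a closed form driven by the
cause-past covariance seen through the coupling vector b:

* Granger causality   GC  = 1/2 ln(sigma'^2 / sigma^2), the log residual
  variance ratio of the reduced (own-past-only) and full regressions;
* Transfer entropy    TE  = 1/2 ln((b' Sigma_{Xp2|Xp1} b + s) / s), with
  the *conditional* covariance of the cause past given the effect past
  (a Schur complement) — TE marginalizes the cause, it does not cut it;
* Dynamic causal strength DCS = 1/2 ln((b' Sigma_{Xp2} b + s) / s), the
  interventional version: the cause past is replaced by an independent
  copy with its current *marginal* joint distribution, preserving the
  dependence between successive past samples;
* relative DCS uses an independent copy drawn from a pre-event
  *reference* marginal (mean mu_ref, covariance Sigma_ref), so it also
  reacts to deterministic event-related mean changes:

      rDCS = 1/2 [ ln(v/s) + (s + b' Sigma_t b + (b' dmu)^2) / v - 1 ],
      v = b' Sigma_ref b + s,   dmu = mu_{Xp2,t} - mu_ref.

The natural logarithm is used throughout (nats) and the 1/2 factor is
applied uniformly so GC and TE coincide for stationary Gaussian data in
the large-sample limit.  A Monte-Carlo estimator of the defining expected
KL divergences is provided as an independent numerical cross-check of the
closed forms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .estimation import (PeriEventMoments, TimeVaryingFit, compute_moments,
                         design_tensor, fit_reduced, fit_svar,
                         moments_from_design)
from .events import EventEnsemble
from .svar import SVARModel, PopulationMoments, population_moments

logger = logging.getLogger("pericausal")

DIRECTIONS = ("2->1", "1->2")
MEASURES = ("gc", "te", "dcs", "rdcs")

# absolute tolerance (relative to scale) below which a negative quadratic
# form is treated as numerical zero
_PSD_TOL = 1e-8


@dataclass
class ReferenceMoments:
    """Time-averaged pre-event statistics of the cause lag vector."""

    window: tuple[int, int]     # [start, end] in peri-event time, inclusive
    mu: np.ndarray              # (p,)
    cov: np.ndarray             # (p, p)


def reference_from_moments(moments: PeriEventMoments, cause_channel: int,
                           window: tuple[int, int]) -> ReferenceMoments:
    """Average the cause-past mean and covariance over a peri-event window."""
    lo, hi = window
    mask = (moments.peri_times >= lo) & (moments.peri_times <= hi)
    if not mask.any():
        raise ValueError(f"reference window {window} contains no peri-event "
                         "times with full lag vectors")
    if hi >= 0:
        logger.warning("reference window %s extends to t' >= 0; it should "
                       "precede the event", window)
    mu = moments.mean_past(cause_channel)[mask].mean(axis=0)
    cov = moments.cov_past(cause_channel, cause_channel)[mask].mean(axis=0)
    return ReferenceMoments(window=(lo, hi), mu=mu, cov=cov)


def default_reference_window(moments: PeriEventMoments,
                             length: int = 16) -> tuple[int, int]:
    """Earliest ``length`` admissible peri-event samples."""
    t0 = int(moments.peri_times[0])
    return (t0, t0 + length - 1)


# --- closed forms -------------------------------------------------------

def _quad(b: np.ndarray, S: np.ndarray) -> float:
    q = float(b @ S @ b)
    scale = max(1.0, float(np.abs(np.diag(S)).max()) * float(b @ b))
    if q < -_PSD_TOL * scale:
        raise ValueError(
            f"covariance quadratic form is negative ({q:.3g}); "
            "matrix is not PSD within tolerance")
    return max(q, 0.0)


def schur_complement(S_cc: np.ndarray, S_ce: np.ndarray,
                     S_ee: np.ndarray) -> np.ndarray:
    """Cov[cause past | effect past] = S_cc - S_ce S_ee^{-1} S_ce'."""
    try:
        X = np.linalg.solve(S_ee, S_ce.T)
    except np.linalg.LinAlgError:
        X = np.linalg.pinv(S_ee, rcond=1e-10) @ S_ce.T
    C = S_cc - S_ce @ X
    return 0.5 * (C + C.T)


def transfer_entropy_t(b: np.ndarray, cond_cov: np.ndarray,
                       innov_var: float) -> float:
    """TE at one t' from the coupling vector, the conditional covariance
    of the cause past given the effect past, and the full-model
    innovation variance."""
    if innov_var <= 0:
        raise ValueError("innovation variance must be positive")
    return 0.5 * np.log1p(_quad(b, cond_cov) / innov_var)


def granger_causality_t(var_reduced: float, var_full: float) -> float:
    """GC at one t'; may be slightly negative in finite samples and is
    returned raw, never clipped."""
    if var_reduced <= 0 or var_full <= 0:
        raise ValueError("residual variances must be positive")
    return 0.5 * np.log(var_reduced / var_full)


def dynamic_causal_strength_t(b: np.ndarray, marg_cov: np.ndarray,
                              innov_var: float) -> float:
    """DCS at one t' (marginal cause-past covariance; joint independent
    copy intervention)."""
    if innov_var <= 0:
        raise ValueError("innovation variance must be positive")
    return 0.5 * np.log1p(_quad(b, marg_cov) / innov_var)


def relative_dcs_t(b: np.ndarray, mu_cause: np.ndarray, marg_cov: np.ndarray,
                   innov_var: float, ref: ReferenceMoments) -> float:
    """rDCS at one t' (independent copy drawn from the reference-state
    marginal of the cause past)."""
    if innov_var <= 0:
        raise ValueError("innovation variance must be positive")
    v = _quad(b, ref.cov) + innov_var
    if v <= 0:
        raise ValueError("reference predictive variance is not positive")
    dmu = float(b @ (np.asarray(mu_cause) - ref.mu))
    num = innov_var + _quad(b, marg_cov) + dmu ** 2
    return 0.5 * (np.log(v / innov_var) + num / v - 1.0)


# --- Monte-Carlo oracle --------------------------------------------------

INTERVENTIONS = ("conditional_marginalize", "joint_copy", "reference_copy")


def mc_kl_oracle(a: np.ndarray, b: np.ndarray, k: float, innov_var: float,
                 mu_past: np.ndarray, cov_past: np.ndarray,
                 intervention: str, ref: ReferenceMoments | None = None,
                 n_samples: int = 100_000, seed: int = 0
                 ) -> tuple[float, float]:
    """Monte-Carlo estimate (value, standard error) of the expected KL
    divergence defining TE / DCS / rDCS for one Gaussian model row.

    ``mu_past``/``cov_past`` describe the joint of
    [effect past (p), cause past (p)].  Pasts are sampled from that joint,
    the effect present is sampled from the full conditional, and the exact
    log-density ratio between the full conditional and the intervened
    conditional is averaged.  This estimator is independent of the
    closed-form route: it never forms the aggregated formulas above.
    """
    if intervention not in INTERVENTIONS:
        raise ValueError(f"unknown intervention {intervention!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    p = len(a)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    W = rng.multivariate_normal(mu_past, cov_past, size=n_samples,
                                method="svd")
    W1, W2 = W[:, :p], W[:, p:]
    mean_full = W1 @ a + W2 @ b + k
    x1 = mean_full + np.sqrt(innov_var) * rng.standard_normal(n_samples)

    mu1, mu2 = mu_past[:p], mu_past[p:]
    S11 = cov_past[:p, :p]
    S22 = cov_past[p:, p:]
    S21 = cov_past[p:, :p]
    if intervention == "conditional_marginalize":
        G = np.linalg.pinv(S11, rcond=1e-10) @ S21.T        # (p, p)
        mu2_given_1 = mu2 + (W1 - mu1) @ G
        mean_q = W1 @ a + mu2_given_1 @ b + k
        var_q = float(b @ (S22 - S21 @ G) @ b) + innov_var
    elif intervention == "joint_copy":
        mean_q = W1 @ a + float(b @ mu2) + k
        var_q = float(b @ S22 @ b) + innov_var
    else:
        if ref is None:
            raise ValueError("reference_copy needs ReferenceMoments")
        mean_q = W1 @ a + float(b @ ref.mu) + k
        var_q = float(b @ ref.cov @ b) + innov_var

    log_p = -0.5 * (np.log(2 * np.pi * innov_var)
                    + (x1 - mean_full) ** 2 / innov_var)
    log_q = -0.5 * (np.log(2 * np.pi * var_q) + (x1 - mean_q) ** 2 / var_q)
    ratio = log_p - log_q
    return float(ratio.mean()), float(ratio.std(ddof=1) / np.sqrt(n_samples))


# --- timecourses ---------------------------------------------------------

@dataclass
class CausalityResult:
    """Per-t' GC/TE/DCS/rDCS for both directions with bootstrap spread."""

    peri_times: np.ndarray
    values: dict = field(default_factory=dict)   # values[direction][measure]
    sd: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        rows = []
        for direction in DIRECTIONS:
            for measure in MEASURES:
                vals = self.values[direction][measure]
                sds = self.sd.get(direction, {}).get(measure)
                for i, tp in enumerate(self.peri_times):
                    rows.append((int(tp), direction, measure, vals[i],
                                 np.nan if sds is None else sds[i]))
        return pd.DataFrame(rows, columns=["t_prime", "direction", "measure",
                                           "value", "sd"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        out = {"meta": self.meta}
        for direction in DIRECTIONS:
            out[direction] = {
                m: {"mean": float(np.mean(self.values[direction][m])),
                    "max": float(np.max(self.values[direction][m]))}
                for m in MEASURES}
        return out

    def save_summary(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.summary(), f, indent=2, default=str)


def _direction_channels(direction: str) -> tuple[int, int]:
    """(cause, effect) channels."""
    if direction == "2->1":
        return 2, 1
    if direction == "1->2":
        return 1, 2
    raise ValueError(f"unknown direction {direction!r}")


def measures_from_moments(moments: PeriEventMoments,
                          fit: TimeVaryingFit | None = None,
                          refs: dict[str, ReferenceMoments] | None = None,
                          ref_window: tuple[int, int] | None = None,
                          p_reduced: int | None = None,
                          ridge: float = 0.0) -> dict:
    """All four measures for both directions from one set of moments.

    Returns ``{direction: {measure: (n_t,) array}}``.  ``refs`` maps
    direction -> ReferenceMoments; if absent they are built from
    ``ref_window`` (default: the earliest 16 admissible samples).
    """
    if fit is None:
        fit = fit_svar(moments, ridge=ridge)
    if refs is None:
        window = (default_reference_window(moments) if ref_window is None
                  else ref_window)
        refs = {d: reference_from_moments(moments, _direction_channels(d)[0],
                                          window)
                for d in DIRECTIONS}
    out: dict = {}
    for direction in DIRECTIONS:
        cause, effect = _direction_channels(direction)
        _, b_coef, _, s_full = fit.own_cross(effect)
        red = fit_reduced(moments, effect, p_reduced, ridge=ridge)
        S_cc = moments.cov_past(cause, cause)
        S_ce = moments.cov_past(cause, effect)
        S_ee = moments.cov_past(effect, effect)
        mu_c = moments.mean_past(cause)
        ref = refs[direction]
        n_t = moments.n_t
        vals = {m: np.empty(n_t) for m in MEASURES}
        for i in range(n_t):
            cond = schur_complement(S_cc[i], S_ce[i], S_ee[i])
            vals["te"][i] = transfer_entropy_t(b_coef[i], cond, s_full[i])
            vals["gc"][i] = granger_causality_t(red.s[i], s_full[i])
            vals["dcs"][i] = dynamic_causal_strength_t(
                b_coef[i], S_cc[i], s_full[i])
            vals["rdcs"][i] = relative_dcs_t(
                b_coef[i], mu_c[i], S_cc[i], s_full[i], ref)
        out[direction] = vals
    return out


def causality_timecourse(ensemble: EventEnsemble, p: int,
                         ref_window: tuple[int, int] | None = None,
                         n_boot: int = 100, seed: int = 0,
                         p_reduced: int | None = None,
                         ridge: float = 0.0) -> CausalityResult:
    """Full pipeline on one ensemble: moments, fits, all measures in both
    directions, and bootstrap standard deviations.

    The reference windows for rDCS are frozen from the original ensemble
    and reused for every bootstrap resample, so the bootstrap spread
    reflects estimation noise at fixed reference state.
    """
    Z, t_idx = design_tensor(ensemble, p)
    peri = ensemble.peri_event_time[t_idx]
    moments = moments_from_design(Z, p, t_idx, peri)
    if ensemble.n_trials < 2 * p + 3:
        raise ValueError(f"need at least {2 * p + 3} trials for order {p}")
    window = (default_reference_window(moments) if ref_window is None
              else ref_window)
    refs = {d: reference_from_moments(moments, _direction_channels(d)[0],
                                      window)
            for d in DIRECTIONS}
    values = measures_from_moments(moments, refs=refs, p_reduced=p_reduced,
                                   ridge=ridge)

    sd: dict = {}
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        boots = {d: {m: np.empty((n_boot, moments.n_t)) for m in MEASURES}
                 for d in DIRECTIONS}
        n = ensemble.n_trials
        for ib in range(n_boot):
            idx = rng.integers(0, n, size=n)
            bm = moments_from_design(Z[idx], p, t_idx, peri)
            bv = measures_from_moments(bm, refs=refs, p_reduced=p_reduced,
                                       ridge=ridge)
            for d in DIRECTIONS:
                for m in MEASURES:
                    boots[d][m][ib] = bv[d][m]
        sd = {d: {m: boots[d][m].std(axis=0, ddof=1) for m in MEASURES}
              for d in DIRECTIONS}

    return CausalityResult(
        peri_times=peri,
        values=values,
        sd=sd,
        meta={"alignment": ensemble.alignment,
              "aligned_on": ensemble.aligned_on,
              "p": p, "p_reduced": p_reduced or p,
              "reference_window": list(window),
              "n_trials": ensemble.n_trials,
              "n_boot": int(n_boot), "seed": int(seed)},
    )


# --- exact (population) measures -----------------------------------------

def population_causality(model: SVARModel,
                         ref_window: tuple[int, int] | None = None,
                         pop: PopulationMoments | None = None,
                         init: str = "stationary") -> CausalityResult:
    """Closed-form measure timecourses from the model's exact population
    moments — no estimation noise.  GC equals TE at the population level.

    ``ref_window`` is an inclusive [start, end] index range on the model's
    time axis used for the rDCS reference state (default: first 16 steps).
    Values are produced for t = 1 .. T-1, where past-state statistics
    exist.
    """
    if pop is None:
        pop = population_moments(model, init=init)
    p = model.order
    T = model.n_times
    if ref_window is None:
        ref_window = (1, min(16, T - 1))
    lo, hi = ref_window
    ts = np.arange(1, T)

    def past_block(t, cause):
        mu, P = pop.past_stats(t)
        sl_c = slice(0, p) if cause == 1 else slice(p, 2 * p)
        return mu[sl_c], P[sl_c, sl_c]

    refs = {}
    for d in DIRECTIONS:
        cause = _direction_channels(d)[0]
        mus, covs = zip(*(past_block(t, cause) for t in range(lo, hi + 1)))
        refs[d] = ReferenceMoments(window=(lo, hi),
                                   mu=np.mean(mus, axis=0),
                                   cov=np.mean(covs, axis=0))

    values: dict = {}
    for d in DIRECTIONS:
        cause, effect = _direction_channels(d)
        vals = {m: np.empty(len(ts)) for m in MEASURES}
        for i, t in enumerate(ts):
            mu, P = pop.past_stats(t)
            sl_c = slice(0, p) if cause == 1 else slice(p, 2 * p)
            sl_e = slice(0, p) if effect == 1 else slice(p, 2 * p)
            S_cc, S_ce, S_ee = P[sl_c, sl_c], P[sl_c, sl_e], P[sl_e, sl_e]
            if effect == 1:
                b = model.coeff_b[t]
                s = model.innov_var_1[t]
            else:
                b = model.coeff_c[t]
                s = model.innov_var_2[t]
            cond = schur_complement(S_cc, S_ce, S_ee)
            vals["te"][i] = transfer_entropy_t(b, cond, s)
            vals["gc"][i] = vals["te"][i]
            vals["dcs"][i] = dynamic_causal_strength_t(b, S_cc, s)
            vals["rdcs"][i] = relative_dcs_t(b, mu[sl_c], S_cc, s, refs[d])
        values[d] = vals
    return CausalityResult(peri_times=ts, values=values, sd={},
                           meta={"population": True,
                                 "reference_window": list(ref_window)})
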