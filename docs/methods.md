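# Methods

## Model

`pericausal` treats peri-event trials as independent realizations of a
time-inhomogeneous bivariate SVAR(p) with Gaussian innovations and no
contemporaneous effects (see README for the equations). The key modeling
assumptions are:

* values at each peri-event time t′ are sampled i.i.d. across trials
  from the same (t′-dependent) distribution — a different linear model
  holds in every one-sample time window;
* innovations are independent across time, channels and trials; their
  means k_t and variances σ²_t may vary with t′, which is how
  deterministic event waveforms enter the model;
* all lag vectors are ordered most-recent-first,
  `X_{p,t} = [X_{t−1}, …, X_{t−p}]`, everywhere in the package.

No unobserved confounding is assumed when the measures are read causally.
Only the bivariate case is implemented; conditional (>2 channel)
extensions would add the other channels' pasts to every conditioning set
but are not exercised here.

## Estimation

At each t′ the present values and the stacked lag vectors of both
channels form a (2p+2)-dimensional vector whose cross-trial mean and
covariance (unbiased, n−1 denominator) are computed once per ensemble.
Everything else is a function of these moments:

* full-model coefficients by OLS of the present value on both stacked
  pasts plus an intercept; the intercept is the innovation-mean estimate
  k̂_t and the residual variance (denominator n − 2p − 1) the innovation
  variance σ̂²_t;
* the reduced model re-estimates the effect channel on its own past
  only. Its order defaults to p so that GC and TE stay comparable; a
  smaller order can be requested;
* near-singular second moments (the low-noise, strongly synchronized
  regime) fall back to a pseudo-inverse with relative tolerance 1e−10;
  an optional ridge term (default 0) can be added for extreme cases.

### Order selection

The time-varying BIC sums the per-time, per-channel Gaussian likelihood
term over the candidate fit and penalizes the full per-time parameter
count:

    BIC(p) = Σ_{t′, ch} n·ln σ̃²_ML(t′, ch; p)
             + [n_t · 2 · (2p + 2)] · ln(2 · n · n_t)

where n is the trial count, n_t the number of scored time points, σ̃²_ML
the maximum-likelihood residual variance, and 2p+2 counts coefficients,
intercept and variance per channel and time. All candidate orders
(default 1..8) are scored on the identical observation set by trimming
lags to the largest candidate; ties go to the smallest order. The exact
penalty form is a package choice; order recovery on the perturbation
scenario is insensitive to reasonable variants because the likelihood
term dominates.

## Measures

All four measures are in nats with a uniform ½ factor. The Gaussian
closed forms (README) follow from the expected-KL definitions:

* TE marginalizes the cause past inside the observational distribution,
  so the cause-past covariance it sees is conditional on the effect past
  (Schur complement). Consequences that the package verifies: TE = 0
  when the cause is a deterministic function of the effect (perfect
  synchrony), and TE ≤ DCS always.
* DCS replaces the cause past with an independent copy of its current
  joint marginal. The copy is *jointly* distributed — it preserves the
  dependence among the cause's successive past samples — which makes DCS
  coincide with TE (both equal the cause-past/effect-present mutual
  information) when the effect has no self-dependence and the effect
  past carries no information about the cause past.
* rDCS replaces the copy's distribution by a reference (pre-event)
  marginal N(μ_ref, Σ_ref). Its closed form was derived as the expected
  Gaussian KL between N(aᵀX¹p + bᵀX²p + k, σ²) and the intervened
  predictive N(aᵀX¹p + bᵀμ_ref + k, bᵀΣ_ref b + σ²), and is additionally
  cross-checked at run time against a Monte-Carlo estimator of the
  defining expected KL (below). rDCS = DCS exactly when the cause is
  stationary, and rDCS = 0 when the coupling vanishes.
* TE and DCS are bitwise invariant to innovation-mean profiles (their
  closed forms involve only coefficients, covariances and variances);
  rDCS increases by ½(bᵀΔμ)²/v wherever the cause mean departs from the
  reference, which is precisely why it can see deterministic transients.

Finite-sample GC may be slightly negative and is returned unclipped;
the analytic TE/DCS/rDCS are nonnegative by construction (quadratic
forms are clipped at zero within a PSD tolerance of 1e−8 relative to
scale; genuinely negative quadratic forms raise an error).

### Reference state

The reference moments are the time-averaged mean and covariance of the
cause lag vector over a pre-event window — averaging is valid because
the reference period is assumed stationary. The window is configurable
and defaults to the earliest 16 admissible samples of the peri-event
axis; a warning is emitted if it reaches t′ ≥ 0. For bootstrap spreads,
reference moments are frozen from the original ensemble so the resample
spread reflects estimation noise at a fixed reference state.

### Monte-Carlo oracle

`mc_kl_oracle` samples the stacked pasts from their joint Gaussian,
samples the effect present from the full conditional, and averages the
exact log-density ratio between the full conditional and the intervened
conditional (`conditional_marginalize` for TE, `joint_copy` for DCS,
`reference_copy` for rDCS). It never forms the aggregated closed-form
expressions, so it is an independent numerical check; the test suite
requires agreement within 3 MC standard errors at 1e5 samples on
randomized SVAR(1)/SVAR(2) models, including a nonstationary-mean case
where rDCS ≠ DCS.

## Event selection and alignment

Detection conventions (fixed in one place and used consistently):
0-based sample indices; windows `(pre, post)` closed on both ends with
t′ = 0 at the reference sample; threshold d₀ times the standard
deviation of the *whole* detection signal, strict inequality; the
detection signal is a single configured channel, raw or filtered by a
causal FIR (so the selection indicator depends only on samples at
t′ ≤ 0). Arbitrary multi-channel reductions (e.g. a mean of rectified
filtered channels) can be used by passing the precomputed detection
signal directly to `detect_reference_points` — the function does not
care how the statistic was built.

`local_peak` mode keeps strict local maxima among above-threshold
samples; on plateaus of equal-height neighbors the earliest sample wins
(determinism), and peaks are thinned greedily in time so consecutive
reference points are at least `min_separation` apart.
`min_separation` defaults to the window length, which prevents
overlapping trials. `all_above` keeps every above-threshold sample
(smoothed alignment); local-peak references are by construction a subset
of these. Points whose full window would cross a recording edge are
dropped; zero detections is a warning, not an error.

Single-time selection models thresholding applied to a perfectly aligned
ensemble: trials whose chosen-channel value at t′ = 0 exceeds d₀·SD are
kept. Selecting on the cause leaves the effect's conditional — and hence
coupling estimates and the 2→1 measures — recoverable; selecting on the
effect conditions on the regression target and biases estimates at
t′ ≤ 0. The practical recommendation implemented in the pipeline is to
compare directions with each aligned on its putative cause. In the
simulated perturbation scenario at 500 events, single-time selection on
the *effect* channel at the default d₀ = 3 retains no trials (the effect
waveform peaks near 10 while 3·SD ≈ 16), so effect-aligned analyses use
the detection pipeline (threshold + local-peak alignment) instead; this
is a property of the scenario's signal-to-threshold geometry, not of the
estimators.

## Synthetic scenarios

*Perturbation events.* A stable SVAR(4) with uni-directional 2→1
coupling (a = [−0.55, −0.45, −0.55, −0.85], b = [1.4, −0.3, 1.5, 1.7],
c = 0, d = [0.9, −0.25, 0, 0.25], unit innovation variances) whose
cause-channel innovation mean follows a Morlet waveform
H·exp(−(αx)²/2)·cos(5αx) with H = 4, α = 2/25 on the integer grid
x = −50..50 (101 samples, interpreted as milliseconds at 1 kHz). Events
sit on a regular 260-sample grid (the spacing implied by the published
scenario's duration and event count; jitter is disabled by default) and
the exact centers are returned for ground-truth alignment. Peri-event
windows are 200 samples, t′ = −99..+100. Validation uses 500 events — a
tenth of the published count — which is ample for order recovery and
all measure contrasts.

*Coupled oscillators.* Two damped harmonic oscillators, x (ζ = 0.015722,
period 200 samples, noise variance 0.02) uni-directionally driving y
(ζ = 0.2, period 20, coupling 0.098, noise variance 0.005), integrated
by the Euler method at unit step from standard-normal initial states;
the first 500 samples are discarded so y has locked to x. The Euler
scheme is exactly a stationary SVAR(2) (the rewriting is provided and
verified bit-for-bit), so SVAR-based measures apply without model error.
The synchrony study reduces the cause noise variance by a factor 0.1
inside a 100-sample window centered in the retained segment — the
interval and factor are configuration (the source experiment does not
print them) — and compares interval-averaged TE against a control run at
200 trials.

*Uniform-innovation SVAR(1).* A lag-1 model with Uniform(−1, 1)
innovations used to show that selection-recoverability is not an
artifact of Gaussianity: the cross-past regression slope at t′ = 0
survives cause-selection and breaks under effect-selection.

What the generators do **not** emulate: 1/f background spectra,
measurement noise, event-amplitude and inter-event-interval variability,
bidirectional coupling, and nonlinearity. Passing tests therefore
demonstrate correctness of the estimators and the theoretical properties
of the measures under the stated model, not robustness to violations of
it on real recordings.

## Numerical and design choices

* Simulation: the first p samples start at zero and a burn-in (default
  500 samples) is discarded; per-trial RNG substreams are spawned from
  the master seed by trial index so any trial is reproducible in
  isolation; stationary-coefficient models are refused if the 2p×2p
  companion spectral radius is ≥ 1.
* Exact (population) measure values are computed by propagating the
  state mean/covariance recursion forward from the stationary fixed
  point (discrete Lyapunov initialization); these "no estimation noise"
  curves back the exactness tests (TE/DCS mean-invariance, rDCS = 0
  under coupling loss, TE ≤ DCS).
* In the worked example of a single innovation-mean pulse of size α on
  the cause of an SVAR(1), the effect mean is E[X¹_{t₀+1+j}] = αb·aʲ —
  the value αb appears one step after the pulse with exponent zero; the
  package's tests pin this to the brute-force linear recursion.
* Bootstrap spread: trials resampled with replacement at fixed trial
  count, default 100 resamples, all seeds logged in result metadata.
* Validation problem sizes (package defaults, chosen to run the whole
  suite in minutes on one CPU): 500 perturbation events, 200 oscillator
  trials, 100 bootstrap resamples for event-sensitivity checks, 1e5
  Monte-Carlo samples for the KL oracle. The `--paper-scale` experiment
  flag restores the published sizes (5000 events, 2000 trials, 100
  bootstraps).

## Known limitations

Bivariate only; linear-Gaussian estimation (nonlinear dynamics are only
captured to the extent a time-varying linear model approximates them);
no significance testing or surrogate nulls — the bootstrap quantifies
estimator spread, not a null distribution; the reduced model for GC uses
a finite own-past order, which is misspecified under bidirectional
coupling; selection bias is characterized and sidestepped by
putative-cause alignment, not corrected; template-matching detection is
out of scope.
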