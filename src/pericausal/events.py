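"""Event selection and alignment.

Spontaneous transient events are located in a continuous recording by
thresholding a detection signal (the raw channel or a causally filtered
version of it), choosing reference points, and cutting fixed-length
peri-event windows around them.  The resulting trials-by-time-by-channel
ensemble is the unit of all downstream estimation.

Conventions (used consistently across the package):

* sample indices are 0-based; peri-event windows are closed on both ends,
  so ``window=(pre, post)`` yields ``pre + post + 1`` samples with
  peri-event time t' = 0 at the reference sample;
* the detection threshold is ``d0`` times the standard deviation of the
  *whole* detection signal;
* detection is causal: whether ``t`` is a reference point never depends on
  samples strictly after ``t``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import signal as _sig

logger = logging.getLogger("pericausal")

ALIGNMENTS = ("ground_truth", "single_time", "smoothed", "local_peak")


@dataclass
class EventEnsemble:
    """Peri-event trials: ``data`` has shape (n_trials, n_times, 2).

    ``peri_event_time`` is the integer t' axis (0 at the reference point
    for aligned ensembles; a plain 0..T-1 axis for raw simulations).
    ``ref_times`` are per-trial sample indices into the source recording,
    absent for purely simulated ground-truth ensembles.
    """

    data: np.ndarray
    peri_event_time: np.ndarray
    ref_times: np.ndarray | None = None
    alignment: str = "ground_truth"
    aligned_on: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.peri_event_time = np.asarray(self.peri_event_time, dtype=int)
        if self.data.ndim != 3 or self.data.shape[2] != 2:
            raise ValueError("data must have shape (n_trials, n_times, 2)")
        if self.data.shape[0] < 1:
            raise ValueError("ensemble needs at least one trial")
        if len(self.peri_event_time) != self.data.shape[1]:
            raise ValueError("peri_event_time length does not match data")
        if self.alignment not in ALIGNMENTS:
            raise ValueError(f"unknown alignment tag {self.alignment!r}")
        if self.ref_times is not None:
            self.ref_times = np.asarray(self.ref_times, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def time_index(self, tprime: int) -> int:
        """Index on the time axis of peri-event time ``tprime``."""
        idx = np.nonzero(self.peri_event_time == tprime)[0]
        if idx.size == 0:
            raise KeyError(f"peri-event time {tprime} not in window")
        return int(idx[0])

    # --- persistence -----------------------------------------------------

    def to_hdf5(self, path, seed: int | None = None,
                model_hash: str | None = None) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("peri_event_time", data=self.peri_event_time)
            if self.ref_times is not None:
                f.create_dataset("ref_times", data=self.ref_times)
            f.attrs["alignment"] = self.alignment
            f.attrs["aligned_on"] = -1 if self.aligned_on is None else self.aligned_on
            if seed is not None:
                f.attrs["seed"] = seed
            if model_hash is not None:
                f.attrs["model_hash"] = model_hash

    @classmethod
    def from_hdf5(cls, path) -> "EventEnsemble":
        with h5py.File(path, "r") as f:
            ref = f["ref_times"][:] if "ref_times" in f else None
            aligned_on = int(f.attrs.get("aligned_on", -1))
            return cls(
                data=f["data"][:],
                peri_event_time=f["peri_event_time"][:],
                ref_times=ref,
                alignment=str(f.attrs.get("alignment", "ground_truth")),
                aligned_on=None if aligned_on < 0 else aligned_on,
            )


@dataclass
class DetectionConfig:
    """Settings for event detection on one channel of a recording.

    Either explicit FIR ``taps`` or a (``band``, ``order``, ``fs``) design
    may be given; with neither, the raw channel is the detection signal.
    """

    threshold_sd: float = 3.0
    mode: str = "local_peak"               # "all_above" | "local_peak"
    window: tuple[int, int] = (99, 100)    # (pre, post) samples around t'=0
    min_separation: int | None = None      # defaults to the window length
    channel: int = 2                       # 1-based channel used for detection
    taps: np.ndarray | None = None
    band: tuple[float, float] | None = None
    order: int | None = None
    fs: float | None = None

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0 and np.isfinite(self.threshold_sd):
            raise ValueError("threshold_sd d0 must be positive")
        if self.mode not in ("all_above", "local_peak"):
            raise ValueError(f"unknown detection mode {self.mode!r}")
        if self.channel not in (1, 2):
            raise ValueError("detection channel must be 1 or 2")
        if self.min_separation is None:
            # default: no overlapping trials
            self.min_separation = self.window[0] + self.window[1] + 1
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")

    @property
    def window_length(self) -> int:
        return self.window[0] + self.window[1] + 1


def design_fir(band: tuple[float, float], order: int, fs: float) -> np.ndarray:
    """Causal band-pass FIR taps (``order + 1`` coefficients)."""
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(
            f"band {band} outside the open interval (0, fs/2) = (0, {fs / 2})")
    return _sig.firwin(order + 1, [lo, hi], pass_zero=False, fs=fs)


def fir_filter(x: np.ndarray, config: DetectionConfig | None = None, *,
               taps: np.ndarray | None = None,
               band: tuple[float, float] | None = None,
               order: int | None = None, fs: float | None = None) -> np.ndarray:
    """Apply a causal FIR filter to a 1-D signal.

    Output has the same length as the input, and output[t] depends only on
    input samples at times <= t (zero initial conditions), which is what the
    selection theory requires of the detection statistic.
    """
    if config is not None:
        taps = config.taps if taps is None else taps
        band = config.band if band is None else band
        order = config.order if order is None else order
        fs = config.fs if fs is None else fs
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("fir_filter expects a 1-D signal")
    if taps is None:
        if band is None:
            raise ValueError("give either explicit taps or (band, order, fs)")
        taps = design_fir(band, int(order), float(fs))
    return _sig.lfilter(np.asarray(taps, dtype=float), [1.0], x)


def detection_signal(recording: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Detection statistic D: the configured channel, FIR-filtered if a
    filter is configured, raw otherwise."""
    x = np.asarray(recording, dtype=float)[:, config.channel - 1]
    if config.taps is not None or config.band is not None:
        return fir_filter(x, config)
    return x


def detect_reference_points(det: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Reference points from a detection signal.

    The threshold is ``d0`` times the SD of the whole signal (strict
    inequality).  ``all_above`` returns every above-threshold sample
    (smoothed alignment); ``local_peak`` returns strict local maxima of the
    detection signal among above-threshold samples, ties broken toward the
    earlier sample, thinned greedily in time so consecutive picks are at
    least ``min_separation`` apart.  Points whose peri-event window would
    run off either end of the recording are dropped.
    """
    det = np.asarray(det, dtype=float)
    thr = config.threshold_sd * det.std()
    above = det > thr
    if config.mode == "all_above":
        cand = np.nonzero(above)[0]
    else:
        # strict rise on the left, non-strict fall on the right: on a
        # plateau of equal-height neighbours the earliest sample wins
        interior = np.zeros_like(above)
        interior[1:-1] = (above[1:-1]
                          & (det[1:-1] > det[:-2])
                          & (det[1:-1] >= det[2:]))
        cand = np.nonzero(interior)[0]
        kept: list[int] = []
        for t in cand:
            if not kept or t - kept[-1] >= config.min_separation:
                kept.append(int(t))
        cand = np.asarray(kept, dtype=int)
    pre, post = config.window
    cand = cand[(cand >= pre) & (cand <= len(det) - 1 - post)]
    if cand.size == 0:
        logger.warning("no reference points detected (threshold %.4g)", thr)
    return cand


def extract_peri_event(recording: np.ndarray, ref_times: np.ndarray,
                       window: tuple[int, int],
                       alignment: str = "ground_truth",
                       aligned_on: int | None = None) -> EventEnsemble:
    """Cut fixed-length windows around the reference points.

    ``window = (pre, post)`` gives trials spanning t' = -pre .. +post.
    Trials are stacked in ``ref_times`` order.
    """
    recording = np.asarray(recording, dtype=float)
    ref_times = np.asarray(ref_times, dtype=int)
    pre, post = window
    bad = ref_times[(ref_times < pre) | (ref_times > len(recording) - 1 - post)]
    if bad.size:
        raise ValueError(
            f"reference points without a full window: {bad.tolist()}")
    trials = np.stack([recording[r - pre:r + post + 1] for r in ref_times])
    return EventEnsemble(
        data=trials,
        peri_event_time=np.arange(-pre, post + 1),
        ref_times=ref_times,
        alignment=alignment,
        aligned_on=aligned_on,
    )


def single_time_selection(ensemble: EventEnsemble, channel: int, d0: float,
                          sd: float | None = None) -> EventEnsemble:
    """Keep only trials whose chosen-channel value at t' = 0 exceeds
    ``d0 * sd``.

    ``sd`` defaults to the SD of that channel pooled over the whole
    ensemble; pass the SD of the source recording when available.  Models
    thresholding applied to a perfectly aligned (ground-truth) ensemble.
    """
    if ensemble.alignment != "ground_truth":
        raise ValueError("single-time selection applies to ground-truth "
                         "aligned ensembles")
    if channel not in (1, 2):
        raise ValueError("channel must be 1 or 2")
    x = ensemble.data[:, ensemble.time_index(0), channel - 1]
    if sd is None:
        sd = float(ensemble.data[:, :, channel - 1].std())
    keep = x > d0 * sd
    if not keep.any():
        raise ValueError(
            f"no trials exceed {d0} SD at t'=0; lower the threshold d0")
    return EventEnsemble(
        data=ensemble.data[keep],
        peri_event_time=ensemble.peri_event_time,
        ref_times=None if ensemble.ref_times is None else ensemble.ref_times[keep],
        alignment="single_time",
        aligned_on=channel,
    )


def bootstrap_ensemble(ensemble: EventEnsemble, n_boot: int, seed: int = 0):
    """Yield ``n_boot`` trial-resampled (with replacement) ensembles,
    each with the original trial count.  Reproducible from ``seed``."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = ensemble.n_trials
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yield replace(
            ensemble,
            data=ensemble.data[idx],
            ref_times=None if ensemble.ref_times is None else ensemble.ref_times[idx],
        )
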