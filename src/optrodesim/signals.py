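"""Evoked-signal statistics for paired LFP / fiber-photometry sessions.

A 40-s session has three segments: 10 s baseline, 20 s stimulation
(3 Hz pulse train), 10 s rest.  The analysis chain is:

* LFP: zero-phase band-pass 0.3-300 Hz; clip fixed-period epochs (default
  333 ms) over the 15-25 s analysis window; average epochs samplewise into
  the evoked response; sum the absolute evoked amplitudes over the first
  30 ms post-stimulus (the "sum-LFP" statistic).
* Photometry: zero-phase 100-Hz low-pass; dF/F = (Fs - F0)/F0 against the
  baseline-window mean F0; mean dF/F over the 15-25 s window (fluorescence
  rises ~5 s after stimulation onset, so this window sits on the plateau).
* Dose-response: ordinary least-squares fits with R^2 between any pair of
  per-session statistics (sum-LFP, mean dF/F, VTA volume, simulated
  fluorescence intensity).

All filters are zero-phase forward-backward Butterworth designs (order
configurable, default 4); the underlying recordings name no filter family.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal
import scipy.stats

from .grid import InvalidParameterError


class DegenerateBaselineError(ValueError):
    """The baseline mean F0 is zero; dF/F is undefined."""


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled trace (volts for LFP, arbitrary units for photometry)."""

    samples: np.ndarray
    rate_hz: float
    start_time_s: float = 0.0
    channel_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate_hz <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidParameterError("samples must be a non-empty 1-D array")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n) / self.rate_hz

    def slice_window(self, window_s: tuple[float, float]) -> np.ndarray:
        """Samples with start <= t < stop; window must lie inside the record."""
        t0, t1 = window_s
        if t1 <= t0:
            raise InvalidParameterError("window must have positive length")
        if t0 < self.start_time_s - 1e-9 or t1 > self.start_time_s + self.duration_s + 1e-9:
            raise InvalidParameterError(
                f"window {window_s} outside record "
                f"[{self.start_time_s}, {self.start_time_s + self.duration_s}] s")
        i0 = int(round((t0 - self.start_time_s) * self.rate_hz))
        i1 = int(round((t1 - self.start_time_s) * self.rate_hz))
        return self.samples[i0:i1]


@dataclass(frozen=True)
class EpochSet:
    """Fixed-period epochs clipped from the analysis window of a trace."""

    epochs: np.ndarray  # (n_epochs, epoch_samples)
    rate_hz: float
    period_s: float
    window_s: tuple[float, float]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def evoked_average(self) -> np.ndarray:
        """Samplewise mean across epochs — the averaged evoked response."""
        return self.epochs.mean(axis=0)


@dataclass(frozen=True)
class PhotometryResult:
    """dF/F trace and its summary statistics."""

    dff: TimeSeries
    f0: float
    mean_dff_15_25: float


@dataclass(frozen=True)
class LinearFitResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def _butter_sos(kind: str, edges, rate_hz: float, order: int):
    nyq = rate_hz / 2.0
    arr = np.atleast_1d(np.asarray(edges, dtype=float))
    if np.any(arr <= 0) or np.any(arr >= nyq):
        raise InvalidParameterError(
            f"filter edges {tuple(arr)} Hz must lie in (0, Nyquist={nyq} Hz)")
    wn = float(arr[0]) if arr.size == 1 else arr
    return scipy.signal.butter(order, wn, btype=kind, fs=rate_hz, output="sos")


def bandpass_lfp(ts: TimeSeries, low_hz: float = 0.3, high_hz: float = 300.0,
                 order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth band-pass (default 0.3-300 Hz), length-preserving."""
    if low_hz >= high_hz:
        raise InvalidParameterError("band-pass requires low < high")
    sos = _butter_sos("bandpass", (low_hz, high_hz), ts.rate_hz, order)
    return replace(ts, samples=scipy.signal.sosfiltfilt(sos, ts.samples))


def lowpass_fluorescence(ts: TimeSeries, cutoff_hz: float = 100.0,
                         order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth low-pass (default 100 Hz) for photometry traces."""
    sos = _butter_sos("lowpass", cutoff_hz, ts.rate_hz, order)
    return replace(ts, samples=scipy.signal.sosfiltfilt(sos, ts.samples))


def dff(ts: TimeSeries, baseline_window_s: tuple[float, float] = (0.0, 10.0),
        mean_window_s: tuple[float, float] = (15.0, 25.0)) -> PhotometryResult:
    """Fractional fluorescence change against the baseline-window mean.

    F0 is the mean over ``baseline_window_s``; the dF/F trace covers the
    full record; ``mean_dff_15_25`` averages dF/F over ``mean_window_s``
    (default 15-25 s, on the plateau of the delayed calcium response).
    """
    baseline = ts.slice_window(baseline_window_s)
    if baseline.size == 0:
        raise InvalidParameterError("baseline window contains no samples")
    f0 = float(baseline.mean())
    if f0 == 0.0:
        raise DegenerateBaselineError("baseline mean F0 is zero")
    trace = replace(ts, samples=(ts.samples - f0) / f0,
                    channel_label=ts.channel_label or "dff")
    mean_win = float(trace.slice_window(mean_window_s).mean())
    return PhotometryResult(dff=trace, f0=f0, mean_dff_15_25=mean_win)


def epoch_average(ts: TimeSeries, period_s: float = 0.333,
                  window_s: tuple[float, float] = (15.0, 25.0)) -> EpochSet:
    """Clip consecutive non-overlapping epochs of ``period_s`` from the window.

    Epochs are aligned to the window start (fixed-period clipping, not
    artifact-triggered).  The number of epochs is
    floor(window_length / period); the epoch length in samples is
    round(period * rate).
    """
    if period_s <= 0:
        raise InvalidParameterError("epoch period must be positive")
    win = ts.slice_window(window_s)
    epoch_len = int(round(period_s * ts.rate_hz))
    if epoch_len < 1:
        raise InvalidParameterError("epoch period shorter than one sample")
    n_epochs = int(np.floor((window_s[1] - window_s[0]) / period_s))
    if n_epochs < 1:
        raise InvalidParameterError("analysis window shorter than one epoch")
    # successive epoch starts at exact multiples of the (possibly fractional-
    # sample) period, rounded per epoch to avoid cumulative drift
    starts = np.round(np.arange(n_epochs) * period_s * ts.rate_hz).astype(int)
    if starts[-1] + epoch_len > win.size:
        n_epochs -= 1
        starts = starts[:-1]
    epochs = np.stack([win[s:s + epoch_len] for s in starts])
    return EpochSet(epochs=epochs, rate_hz=ts.rate_hz, period_s=period_s,
                    window_s=tuple(window_s))


def sum_lfp(epochs: EpochSet, post_window_s: float = 0.030,
            mode: str = "window") -> float:
    """Summed absolute evoked amplitude over the first 30 ms post-stimulus.

    ``mode="window"`` (default) sums |evoked_average| over the first
    ``post_window_s`` of the epoch; ``mode="single"`` takes the absolute
    evoked amplitude at exactly ``post_window_s``.
    """
    n_post = int(round(post_window_s * epochs.rate_hz))
    avg = epochs.evoked_average
    if mode == "window":
        if n_post < 1 or n_post > avg.size:
            raise InvalidParameterError("post-stimulus window outside epoch")
        return float(np.abs(avg[:n_post]).sum())
    if mode == "single":
        if n_post >= avg.size:
            raise InvalidParameterError("post-stimulus sample outside epoch")
        return float(abs(avg[n_post]))
    raise InvalidParameterError("mode must be 'window' or 'single'")


def linfit(x, y) -> LinearFitResult:
    """Ordinary least-squares line with R^2 and two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidParameterError("linfit needs >= 3 paired points")
    if np.all(x == x[0]):
        raise InvalidParameterError("x values are all equal; fit is degenerate")
    res = scipy.stats.linregress(x, y)
    return LinearFitResult(slope=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue**2),
                           p_value=float(res.pvalue) if np.isfinite(res.pvalue) else 1.0)
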