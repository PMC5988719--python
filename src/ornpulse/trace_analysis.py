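"""Quantification of fluorescence traces.

Implements ΔF/F0 in two baselining modes (lowest-quartile mean for
spontaneous "prior" activity; nine-frames-from-onset mean for
stimulation experiments), 2σ threshold event detection and event
frequency, one-sided power spectra with cross-trace averaging,
stimulus-response metrics (ΔF/F0max, post-offset undershoot and
return-to-baseline time), the prior-to-evoked amplitude ratio, and
mean ± SEM trace averaging.

Notes on conventions (the originating protocol leaves these open; they
are fixed and documented here):

* "mean of the 25th percentile" is read as the mean of the lowest
  quartile of samples, i.e. the lowest ``ceil(0.25 * N)`` values.
* The baseline for event detection is the median of the ΔF/F0 series;
  σ is the full-series population standard deviation. A robust
  MAD-based σ is available behind ``robust_sigma=True``.
* An event is a maximal run of consecutive samples above
  ``baseline + multiplier * σ``, reported once at its maximum. A
  constant series has σ = 0 and zero events.
* ΔF/F0 is a fraction internally; reports render it as percent.
* Event frequency is events per second.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .imaging_io import FluorescenceTrace

__all__ = [
    "DFFTrace",
    "EventSet",
    "PowerSpectrum",
    "StimulusProtocol",
    "ResponseMetrics",
    "compute_dff",
    "detect_events",
    "event_frequency",
    "power_spectrum",
    "average_spectra",
    "response_metrics",
    "prior_to_evoked_ratio",
    "average_traces",
]

N_STIM_BASELINE_FRAMES = 9  # frames averaged from stimulation onset for F0


@dataclass
class StimulusProtocol:
    """Light-stimulation windows: ``mode`` is 'pulse' or 'continuous'."""

    mode: str
    onsets: list[float]
    durations: list[float]

    def __post_init__(self) -> None:
        if self.mode not in ("pulse", "continuous"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")
        self.onsets = [float(x) for x in np.atleast_1d(self.onsets)]
        self.durations = [float(x) for x in np.atleast_1d(self.durations)]
        if len(self.durations) == 1 and len(self.onsets) > 1:
            self.durations = self.durations * len(self.onsets)
        if len(self.onsets) != len(self.durations):
            raise ValueError("onsets and durations lengths differ")
        if not self.onsets:
            raise ValueError("protocol needs at least one stimulus window")
        order = np.argsort(self.onsets)
        self.onsets = [self.onsets[i] for i in order]
        self.durations = [self.durations[i] for i in order]
        for on, dur in zip(self.onsets, self.durations):
            if on < 0 or dur <= 0:
                raise ValueError("onsets must be >= 0 and durations > 0")
        for (on1, d1), on2 in zip(
            zip(self.onsets, self.durations), self.onsets[1:]
        ):
            if on1 + d1 > on2:
                raise ValueError(
                    f"overlapping stimulus windows: [{on1}, {on1 + d1}) and onset {on2}"
                )

    @property
    def windows(self) -> list[tuple[float, float]]:
        return [(on, on + dur) for on, dur in zip(self.onsets, self.durations)]

    @property
    def final_offset(self) -> float:
        return self.onsets[-1] + self.durations[-1]


@dataclass
class DFFTrace:
    """Normalized ΔF/F0 series with the baseline that produced it."""

    values: np.ndarray
    f0: float
    mode: str  # 'prior_percentile' | 'stim_onset_frames'
    sample_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ΔF/F0 values must be finite")
        if not (self.f0 > 0):
            raise ValueError("f0 must be > 0")
        if not (self.sample_rate > 0):
            raise ValueError("sample_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class EventSet:
    """Detected events with the threshold that defined them."""

    event_times: np.ndarray
    event_amplitudes: np.ndarray
    sigma: float
    baseline: float
    threshold_multiplier: float = 2.0

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.event_amplitudes = np.asarray(self.event_amplitudes, dtype=float)
        if self.event_times.size != self.event_amplitudes.size:
            raise ValueError("event times and amplitudes lengths differ")
        if np.any(np.diff(self.event_times) < 0):
            raise ValueError("event times must be sorted")

    @property
    def n_events(self) -> int:
        return self.event_times.size

    @property
    def threshold(self) -> float:
        return self.baseline + self.threshold_multiplier * self.sigma


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power shapes differ")
        if np.any(np.diff(self.frequencies) <= 0) or self.frequencies[0] < 0:
            raise ValueError("frequencies must be nonnegative ascending")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be >= 0")


@dataclass
class ResponseMetrics:
    dff_max: float
    undershoot: float
    return_time: float | None  # seconds after final offset; None = not reached
    baseline: float = 0.0


def compute_dff(
    trace: FluorescenceTrace,
    mode: str = "prior",
    protocol: StimulusProtocol | None = None,
    pre_onset_baseline: bool = False,
) -> DFFTrace:
    """Normalize a raw trace to ΔF/F0 = (F - F0) / F0.

    mode='prior': F0 is the mean of the lowest quartile of samples
    (the lowest ``ceil(0.25 * N)`` values); requires N >= 4.

    mode='stim': F0 is the mean of the nine frames starting at the first
    stimulation onset. ``pre_onset_baseline=True`` instead averages the
    nine frames ending at the onset, for protocols where the onset
    frames themselves already carry response.
    """
    F = trace.values
    if mode == "prior":
        if F.size < 4:
            raise ValueError("prior mode needs at least 4 samples")
        k = math.ceil(0.25 * F.size)
        f0 = float(np.sort(F)[:k].mean())
        dff_mode = "prior_percentile"
    elif mode == "stim":
        if protocol is None:
            raise ValueError("stim mode requires a StimulusProtocol")
        onset_idx = int(round(protocol.onsets[0] * trace.sample_rate))
        if pre_onset_baseline:
            start = onset_idx - N_STIM_BASELINE_FRAMES
            if start < 0:
                raise ValueError("not enough frames before onset for the baseline window")
            window = F[start:onset_idx]
        else:
            if onset_idx + N_STIM_BASELINE_FRAMES > F.size:
                raise ValueError(
                    f"need {N_STIM_BASELINE_FRAMES} frames from stimulation onset, "
                    f"trace has {F.size - onset_idx}"
                )
            window = F[onset_idx : onset_idx + N_STIM_BASELINE_FRAMES]
        f0 = float(window.mean())
        dff_mode = "stim_onset_frames"
    else:
        raise ValueError(f"unknown baselining mode {mode!r}")
    if f0 <= 0:
        raise ValueError(f"computed F0 = {f0:.4g} <= 0; input trace looks corrupted")
    return DFFTrace((F - f0) / f0, f0, dff_mode, trace.sample_rate)


def detect_events(
    dff: DFFTrace,
    multiplier: float = 2.0,
    robust_sigma: bool = False,
    min_duration: float = 0.0,
    refractory: float = 0.0,
) -> EventSet:
    """Detect events deviating ``multiplier``·σ from the baseline.

    σ is the population standard deviation of the full ΔF/F0 series
    (or 1.4826·MAD with ``robust_sigma``); the baseline is the series
    median. Each maximal run of consecutive samples above
    ``baseline + multiplier·σ`` is one event, located and measured at
    its maximum. Optional knobs discard runs shorter than
    ``min_duration`` seconds or events within ``refractory`` seconds of
    the previous one.
    """
    x = dff.values
    if x.size < 4:
        raise ValueError("need at least 4 samples to detect events")
    baseline = float(np.median(x))
    if robust_sigma:
        sigma = float(1.4826 * np.median(np.abs(x - baseline)))
    else:
        sigma = float(np.std(x))
    if sigma == 0.0:
        return EventSet(np.array([]), np.array([]), sigma, baseline, multiplier)
    threshold = baseline + multiplier * sigma
    above = x > threshold
    # run boundaries
    edges = np.diff(above.astype(np.int8))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(x.size)
    times, amps = [], []
    last_t = -math.inf
    for s, e in zip(starts, ends):
        if (e - s) / dff.sample_rate < min_duration:
            continue
        i = s + int(np.argmax(x[s:e]))
        t = i / dff.sample_rate
        if t - last_t < refractory:
            continue
        times.append(t)
        amps.append(float(x[i]))
        last_t = t
    return EventSet(np.array(times), np.array(amps), sigma, baseline, multiplier)


def event_frequency(events: EventSet, duration: float) -> float:
    """Events per second over the analysis window."""
    if not (duration > 0):
        raise ValueError("duration must be > 0")
    return events.n_events / duration


def power_spectrum(dff: DFFTrace) -> PowerSpectrum:
    """One-sided periodogram of the mean-subtracted ΔF/F0 series.

    Rectangular window, density normalization: the power summed over
    frequency bins times the bin width equals the series variance
    (Parseval), to floating-point accuracy.
    """
    freqs, power = signal.periodogram(
        dff.values,
        fs=dff.sample_rate,
        window="boxcar",
        detrend="constant",
        scaling="density",
    )
    return PowerSpectrum(freqs, power)


def average_spectra(spectra: list[PowerSpectrum]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and SEM across spectra sharing a frequency grid.

    Returns ``(frequencies, mean_power, sem_power)``; SEM is sd/sqrt(n)
    (ddof=1) and NaN when n == 1.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0].frequencies
    for sp in spectra[1:]:
        if sp.frequencies.shape != f0.shape or not np.allclose(sp.frequencies, f0):
            raise ValueError("spectra have mixed frequency grids (sample rates or lengths differ)")
    P = np.stack([sp.power for sp in spectra])
    mean = P.mean(axis=0)
    if P.shape[0] > 1:
        sem = P.std(axis=0, ddof=1) / math.sqrt(P.shape[0])
    else:
        sem = np.full_like(mean, np.nan)
    return f0, mean, sem


def response_metrics(
    dff: DFFTrace,
    protocol: StimulusProtocol,
    post_window: float = 10.0,
    pre_baseline_window: float = 2.0,
) -> ResponseMetrics:
    """Stimulus-response summary metrics.

    * ``dff_max``: maximum ΔF/F0 within the stimulation windows.
    * pre-stimulus baseline: mean ΔF/F0 over the ``pre_baseline_window``
      seconds before the first onset (0.0 when no pre-onset frames exist).
    * ``undershoot``: (minimum over ``post_window`` after the final
      offset) minus that baseline.
    * ``return_time``: first post-offset time, in seconds after offset,
      at which ΔF/F0 <= baseline; None if not reached in the window.
    """
    fs = dff.sample_rate
    n = dff.n_samples
    if protocol.final_offset > dff.duration + 0.5 / fs:
        raise ValueError("protocol windows extend beyond the trace")
    in_stim = np.zeros(n, dtype=bool)
    t = dff.times
    for on, off in protocol.windows:
        in_stim |= (t >= on - 0.5 / fs) & (t < off - 0.5 / fs)
    if not in_stim.any():
        raise ValueError("no samples fall inside the stimulation windows")
    dff_max = float(dff.values[in_stim].max())

    first_on = int(round(protocol.onsets[0] * fs))
    pre_n = int(round(pre_baseline_window * fs))
    pre = dff.values[max(0, first_on - pre_n) : first_on]
    baseline = float(pre.mean()) if pre.size else 0.0

    off_idx = int(round(protocol.final_offset * fs))
    end_idx = off_idx + int(round(post_window * fs))
    if end_idx > n:
        warnings.warn("post_window extends beyond the trace; truncated", stacklevel=2)
        end_idx = n
    post = dff.values[off_idx:end_idx]
    if post.size == 0:
        return ResponseMetrics(dff_max, math.nan, None, baseline)
    undershoot = float(post.min() - baseline)
    below = np.where(post <= baseline)[0]
    return_time = float(below[0] / fs) if below.size else None
    return ResponseMetrics(dff_max, undershoot, return_time, baseline)


def prior_to_evoked_ratio(events: EventSet, evoked_max: float) -> float:
    """Mean prior-event amplitude above baseline as percent of the evoked maximum.

    Returns NaN (undefined) when there are no events.
    """
    if not (evoked_max > 0):
        raise ValueError("evoked_max must be > 0")
    if events.n_events == 0:
        warnings.warn("no events; prior-to-evoked ratio is undefined", stacklevel=2)
        return math.nan
    return 100.0 * float(np.mean(events.event_amplitudes - events.baseline)) / evoked_max


def average_traces(traces: list[DFFTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SEM band over equally sampled ΔF/F0 traces.

    SEM uses ddof=1 and is NaN for n == 1.
    """
    if not traces:
        raise ValueError("no traces to average")
    n = traces[0].n_samples
    rate = traces[0].sample_rate
    for tr in traces[1:]:
        if tr.n_samples != n:
            raise ValueError("trace length mismatch")
        if tr.sample_rate != rate:
            raise ValueError("trace sample-rate mismatch")
    X = np.stack([tr.values for tr in traces])
    mean = X.mean(axis=0)
    if X.shape[0] > 1:
        sem = X.std(axis=0, ddof=1) / math.sqrt(X.shape[0])
    else:
        sem = np.full_like(mean, np.nan)
    return mean, sem
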