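"""Per-sweep event detection and response measurement.

Paired-recording sweeps are processed here: baseline estimation from the
pre-stimulus window, classification of each trial (sweep x pulse) as an
evoked event or a transmission failure against a multiple of the baseline
noise SD, measurement of the mean response amplitude over a 1-ms window
around the peak of the averaged trace, and screening for amplitude rundown
early in the recording.

Conventions: times are milliseconds from sweep start, samples are 0-based,
a stimulus time is the peak time of the presynaptic action potential, and
``polarity`` is the expected sign of the postsynaptic response (+1 for
depolarizing potentials / outward currents, -1 for inward currents).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "SweepSet",
    "Baseline",
    "TrialLabels",
    "RundownScreen",
    "estimate_baseline",
    "classify_trials",
    "measure_mean_response",
    "mean_from_single_trials",
    "screen_rundown",
]


@dataclass
class SweepSet:
    """A rectangular set of sampled traces from one paired connection.

    Parameters
    ----------
    traces : ndarray, shape (n_sweeps, n_samples)
        Postsynaptic traces in mV (current clamp) or pA (voltage clamp).
    sample_rate : float
        Sampling rate in Hz.
    stim_times : ndarray
        Presynaptic AP times in ms from sweep start, strictly increasing.
    sweep_timestamps : ndarray
        Start time of each sweep in seconds from the start of the experiment.
    clamp_mode : str
        ``"current"`` or ``"voltage"``.
    polarity : int
        Expected response sign, +1 or -1.
    metadata : dict
        Free-form labels (genotype, connection_id, protocol tag, units, ...).
    """

    traces: np.ndarray
    sample_rate: float
    stim_times: np.ndarray
    sweep_timestamps: np.ndarray
    clamp_mode: str = "current"
    polarity: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        self.sweep_timestamps = np.asarray(self.sweep_timestamps, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (n_sweeps, n_samples)")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.stim_times.size and np.any(np.diff(self.stim_times) <= 0):
            raise ValueError("stim_times must be strictly increasing")
        dur = self.traces.shape[1] / self.sample_rate * 1000.0
        if self.stim_times.size and (
            self.stim_times[0] < 0 or self.stim_times[-1] >= dur
        ):
            raise ValueError("stim_times must lie within the sweep")

    @property
    def n_sweeps(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate * 1000.0

    def sample_index(self, t_ms: float) -> int:
        return int(round(t_ms * self.sample_rate / 1000.0))

    def mean_trace(self) -> np.ndarray:
        return self.traces.mean(axis=0)


@dataclass(frozen=True)
class Baseline:
    """Pre-stimulus baseline: mean, SD, and the window they came from."""

    mean: float
    sd: float
    window: tuple[float, float]


@dataclass
class TrialLabels:
    """Per sweep x pulse event/failure labels with trial measurements.

    ``amplitudes`` holds the signed peak (relative to the baseline mean,
    multiplied by polarity so events are positive) for every trial, failures
    included; ``is_event`` marks trials whose amplitude reached the
    detection threshold; ``latencies`` / ``times_to_peak`` are in ms from
    the corresponding stimulus.
    """

    is_event: np.ndarray  # bool (n_sweeps, n_pulses)
    amplitudes: np.ndarray  # float (n_sweeps, n_pulses)
    latencies: np.ndarray  # float (n_sweeps, n_pulses)
    times_to_peak: np.ndarray  # float (n_sweeps, n_pulses)
    threshold: float

    @property
    def failure_fraction(self) -> np.ndarray:
        """Fraction of trials per pulse that failed to evoke a response."""
        return 1.0 - self.is_event.mean(axis=0)

    @property
    def failure_percent(self) -> np.ndarray:
        return 100.0 * self.failure_fraction


@dataclass(frozen=True)
class RundownScreen:
    keep: bool
    decline: float
    slope_per_min: float
    intercept: float
    screenable: bool = True


def estimate_baseline(sweep: np.ndarray, window: tuple[float, float],
                      sample_rate: float) -> Baseline:
    """Mean and SD of a trace over a pre-stimulus window.

    ``window`` is (start_ms, end_ms); at least 20 samples must fall inside.
    """
    sweep = np.asarray(sweep, dtype=float)
    lo, hi = window
    if hi <= lo:
        raise ValueError("baseline window must have positive length")
    i0 = int(round(lo * sample_rate / 1000.0))
    i1 = int(round(hi * sample_rate / 1000.0))
    if i0 < 0 or i1 > sweep.shape[-1]:
        raise ValueError("baseline window outside trace")
    seg = sweep[..., i0:i1]
    if seg.shape[-1] < 20:
        raise ValueError("baseline window has fewer than 20 samples")
    return Baseline(mean=float(np.mean(seg)), sd=float(np.std(seg, ddof=1)),
                    window=(lo, hi))


def baseline_for(sweeps: SweepSet, window: tuple[float, float] | None = None
                 ) -> Baseline:
    """Baseline over all sweeps; default window is the 50 ms before stimulus 1."""
    if window is None:
        end = float(sweeps.stim_times[0])
        window = (max(0.0, end - 50.0), end)
    return estimate_baseline(sweeps.traces, window, sweeps.sample_rate)


def _pulse_windows(sweeps: SweepSet, latency_window: tuple[float, float]
                   ) -> list[tuple[int, int]]:
    lo, hi = latency_window
    if hi <= lo:
        raise ValueError("empty latency window")
    out = []
    for t in sweeps.stim_times:
        i0 = sweeps.sample_index(t + lo)
        i1 = min(sweeps.sample_index(t + hi) + 1, sweeps.n_samples)
        if i1 - i0 < 2:
            raise ValueError("latency window outside trace")
        out.append((i0, i1))
    return out


def classify_trials(sweeps: SweepSet, baseline: Baseline,
                    latency_window: tuple[float, float] = (1.0, 10.0),
                    k: float = 2.5, *, noiseless: bool = False,
                    ttp_bounds: tuple[float, float] | None = (0.8, 8.0)
                    ) -> TrialLabels:
    """Label each (sweep, pulse) trial as event or failure.

    The signed peak within ``latency_window`` after each stimulus, relative
    to the baseline mean, is an event iff ``polarity*deflection >= k*sd``
    and, when ``ttp_bounds`` is set, its 10%-to-peak rise time is consistent
    with a synaptic waveform (noise maxima rise in well under a millisecond,
    synaptic responses over one to several; the bounds can be learned from
    the large events late in a train via :func:`learn_ttp_bounds`). Pass
    ``ttp_bounds=None`` for the bare amplitude criterion. With two equal
    maxima in the window the earlier one is taken. A zero baseline SD is
    refused unless ``noiseless=True`` is passed explicitly.
    """
    if baseline.sd <= 0 and not noiseless:
        raise ValueError(
            "baseline SD is zero; pass noiseless=True to classify noise-free data"
        )
    windows = _pulse_windows(sweeps, latency_window)
    n_sweeps, n_pulses = sweeps.n_sweeps, len(windows)
    amps = np.empty((n_sweeps, n_pulses))
    lat = np.empty((n_sweeps, n_pulses))
    ttp = np.empty((n_sweeps, n_pulses))
    signed = sweeps.polarity * (sweeps.traces - baseline.mean)
    dt_ms = 1000.0 / sweeps.sample_rate
    for j, (i0, i1) in enumerate(windows):
        seg = signed[:, i0:i1]
        ipk = np.argmax(seg, axis=1)  # ties -> earliest
        amps[:, j] = seg[np.arange(n_sweeps), ipk]
        t_pk = (i0 + ipk) * dt_ms
        lat[:, j] = t_pk - sweeps.stim_times[j]
        # time to peak from the 10%-of-peak crossing within the window
        for s in range(n_sweeps):
            thr = 0.1 * seg[s, ipk[s]]
            onset = ipk[s]
            while onset > 0 and seg[s, onset - 1] >= thr:
                onset -= 1
            ttp[s, j] = (ipk[s] - onset) * dt_ms
    threshold = k * baseline.sd
    is_event = amps >= threshold
    if ttp_bounds is not None and baseline.sd > 0:
        is_event &= (ttp >= ttp_bounds[0]) & (ttp <= ttp_bounds[1])
    return TrialLabels(is_event=is_event, amplitudes=amps,
                       latencies=lat, times_to_peak=ttp, threshold=threshold)


def learn_ttp_bounds(labels: TrialLabels, margin: float = 2.0
                     ) -> tuple[float, float]:
    """Time-to-peak bounds from large, unambiguous events.

    Uses trials whose amplitude exceeds twice the detection threshold (as
    the big late-train responses do) and returns their time-to-peak range
    widened by ``margin`` ms on each side.
    """
    big = labels.amplitudes >= 2.0 * labels.threshold
    if not np.any(big):
        raise ValueError("no large events to learn time-to-peak from")
    ttp = labels.times_to_peak[big]
    return max(0.0, float(ttp.min()) - margin), float(ttp.max()) + margin


def _smooth_lowpass(trace: np.ndarray, sample_rate: float,
                    cutoff_hz: float = 1000.0) -> np.ndarray:
    """Zero-phase low-pass used only to locate the peak, never to measure it."""
    nyq = sample_rate / 2.0
    if cutoff_hz >= nyq:
        return trace
    b, a = signal.butter(4, cutoff_hz / nyq)
    return signal.filtfilt(b, a, trace)


def measure_mean_response(sweeps: SweepSet, pulse_index: int,
                          baseline: Baseline | None = None,
                          latency_window: tuple[float, float] = (1.0, 10.0),
                          peak_window_ms: float = 1.0) -> float:
    """Amplitude of the mean response to one pulse of the train.

    The traces are averaged across sweeps (failures included), the peak of
    the average is located within the latency window after the stimulus on a
    1-kHz low-passed copy, and the amplitude is the mean of the *unsmoothed*
    average over a 1-ms window centred on that peak, minus the baseline mean.
    """
    if baseline is None:
        baseline = baseline_for(sweeps)
    windows = _pulse_windows(sweeps, latency_window)
    if not 0 <= pulse_index < len(windows):
        raise IndexError("pulse_index out of range")
    mean = sweeps.mean_trace()
    return _window_amplitude(mean, sweeps.sample_rate, windows[pulse_index],
                             sweeps.polarity, baseline.mean, peak_window_ms)


def _locate_peak(mean: np.ndarray, sample_rate: float,
                 window: tuple[int, int], polarity: int) -> int:
    """Peak sample within a window: smoothed argmax, re-centred on the raw
    trace with midpoint-of-ties so flat tops resolve to their centre."""
    i0, i1 = window
    smooth = _smooth_lowpass(mean, sample_rate)
    ipk = i0 + int(np.argmax(polarity * smooth[i0:i1]))
    r = max(1, int(round(2.0 * sample_rate / 1000.0)))
    j0, j1 = max(i0, ipk - r), min(i1, ipk + r + 1)
    vals = polarity * mean[j0:j1]
    ties = np.nonzero(vals >= vals.max() - 1e-12 * max(1.0, abs(vals.max())))[0]
    return j0 + int(round(ties.mean()))


def _window_amplitude(mean: np.ndarray, sample_rate: float,
                      window: tuple[int, int], polarity: int,
                      base_mean: float, peak_window_ms: float = 1.0) -> float:
    ipk = _locate_peak(mean, sample_rate, window, polarity)
    half = max(1, int(round(peak_window_ms / 2.0 * sample_rate / 1000.0)))
    j0, j1 = max(0, ipk - half), min(mean.shape[0], ipk + half + 1)
    # trapezoidal average == the window integral / width in the continuum
    seg = mean[j0:j1]
    avg = float(np.trapezoid(seg) / (seg.size - 1))
    return float(polarity * (avg - base_mean))


def mean_from_single_trials(labels: TrialLabels,
                            pulse_index: int | None = None) -> float | np.ndarray:
    """Mean of per-trial peak amplitudes, failures included.

    Fallback estimator for connections whose averaged response is too small
    to measure reliably; failures contribute their measured (noise-level)
    amplitudes, not exact zeros.
    """
    if labels.amplitudes.size == 0:
        raise ValueError("no trials")
    means = labels.amplitudes.mean(axis=0)
    if pulse_index is None:
        return means
    return float(means[pulse_index])


def screen_rundown(amplitudes: np.ndarray, timestamps_s: np.ndarray,
                   limit: float = 0.15,
                   window_s: tuple[float, float] = (0.0, 360.0)) -> RundownScreen:
    """Screen a connection for early amplitude rundown.

    A line is fitted to per-sweep amplitude vs time over the screening
    window (default the first 6 min); the fractional decline over the window
    is ``-slope * window_length / intercept``. Connections declining by more
    than ``limit`` are excluded. With fewer than five sweeps inside the
    window the connection is flagged unscreenable rather than silently kept.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    m = (timestamps_s >= window_s[0]) & (timestamps_s <= window_s[1])
    if m.sum() < 5:
        return RundownScreen(keep=False, decline=np.nan, slope_per_min=np.nan,
                             intercept=np.nan, screenable=False)
    t_min = timestamps_s[m] / 60.0
    slope, intercept = np.polyfit(t_min, amplitudes[m], 1)
    span_min = (window_s[1] - window_s[0]) / 60.0
    if intercept <= 0:
        decline = np.inf if slope < 0 else 0.0
    else:
        decline = -slope * span_min / intercept
    return RundownScreen(keep=decline <= limit, decline=float(decline),
                         slope_per_min=float(slope), intercept=float(intercept))
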