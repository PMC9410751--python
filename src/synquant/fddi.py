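"""Frequency-dependent disynaptic inhibition (FDDI) quantification.

A high-frequency AP train in one pyramidal cell (PC1) can recruit an
interposed SOM interneuron whose spikes produce a delayed outward
inhibitory current in a simultaneously recorded neighboring pyramidal cell
(PC2, voltage-clamped so IPSCs are outward-positive). This module averages
the PC2 sweeps, detects the FDDI onset as the earliest sustained
threshold crossing with IPSC-like rise kinetics after the train onset,
and measures peak amplitude, duration at half amplitude, and charge (the
time integral of the outward current). It also classifies each paired
recording as disynaptic (FDDI), monosynaptic (short-latency per-AP inward
currents), both, or unconnected, and compares FDDI occurrence between
cohorts with Pearson's chi-squared test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import SweepSet, Baseline, estimate_baseline, _smooth_lowpass

__all__ = [
    "FDDIMetrics", "OnsetCriteria", "average_outward_current",
    "measure_onset_delay", "fddi_metrics", "classify_pair_connection",
    "occurrence_test",
]


@dataclass(frozen=True)
class OnsetCriteria:
    """Operational definition of 'an outward current with IPSC kinetics'.

    A candidate onset must exceed ``k * baseline.sd`` continuously for
    ``sustained_ms``, begin at least ``min_latency_ms`` after the train
    onset (to exclude monosynaptic contamination), and show a 10-90% rise
    time within ``rise_bounds_ms``.
    """

    k: float = 2.5
    min_latency_ms: float = 5.0
    sustained_ms: float = 5.0
    rise_bounds_ms: tuple[float, float] = (2.0, 20.0)
    rise_lookahead_ms: float = 60.0
    end_sustained_ms: float = 10.0   # return-to-baseline rule for charge


@dataclass
class FDDIMetrics:
    """Onset, peak, half duration, charge and classification of one pair."""

    classification: str            # 'fddi' | 'monosynaptic' | 'both' | 'none'
    onset_delay: float | None      # ms from the first AP of the train
    peak_amplitude: float | None   # pA, baseline-subtracted
    peak_pulse_index: int | None   # AP index at/after which the peak occurs
    half_duration: float | None    # ms, width at half peak
    charge: float | None           # pA*ms, integral of the outward current


def average_outward_current(sweeps: SweepSet) -> np.ndarray:
    """Pointwise mean across sweeps (sum / number of sweeps), failures included."""
    if sweeps.n_sweeps < 1:
        raise ValueError("need at least one sweep")
    return sweeps.mean_trace()


def _sustained_above(x: np.ndarray, thr: float, n: int) -> np.ndarray:
    """Start indices where x stays >= thr for at least n consecutive samples."""
    above = x >= thr
    if n <= 1:
        return np.nonzero(above)[0]
    ok = np.ones(x.size - n + 1, dtype=bool)
    for i in range(n):
        ok &= above[i:i + ok.size]
    return np.nonzero(ok)[0]


def measure_onset_delay(mean_trace: np.ndarray, train_onset_ms: float,
                        baseline: Baseline, sample_rate: float,
                        criteria: OnsetCriteria = OnsetCriteria()
                        ) -> float | None:
    """Earliest IPSC-like sustained outward threshold crossing after the train.

    Returns the delay in ms from ``train_onset_ms``, or ``None`` when no
    qualifying crossing exists (the pair is then classified 'none').
    """
    y = np.asarray(mean_trace, float) - baseline.mean
    dt = 1000.0 / sample_rate
    thr = criteria.k * baseline.sd
    i_min = int(round((train_onset_ms + criteria.min_latency_ms) / dt))
    n_sus = max(1, int(round(criteria.sustained_ms / dt)))
    starts = _sustained_above(y, thr, n_sus)
    starts = starts[starts >= i_min]
    for i0 in starts:
        # 10-90% rise time of the initial upstroke: measured to the first
        # local peak after the crossing (2 ms of sustained non-increase on a
        # smoothed copy), so later summating IPSCs do not inflate the rise
        look = y[i0:i0 + int(criteria.rise_lookahead_ms / dt)]
        if look.size < 3:
            continue
        sm = _smooth_lowpass(look, sample_rate, 500.0)
        flat = max(1, int(round(2.0 / dt)))
        nonrise = np.diff(sm) <= 0
        stop = look.size - 1
        run = 0
        for j, dwn in enumerate(nonrise):
            run = run + 1 if dwn else 0
            if run >= flat:
                stop = j - flat + 1
                break
        local_max = float(look[:stop + 1].max())
        t10 = np.nonzero(look >= 0.1 * local_max)[0]
        t90 = np.nonzero(look >= 0.9 * local_max)[0]
        if t10.size == 0 or t90.size == 0:
            continue
        rise = (t90[0] - t10[0]) * dt
        lo, hi = criteria.rise_bounds_ms
        if lo <= rise <= hi:
            return float(i0 * dt - train_onset_ms)
    return None


def fddi_metrics(mean_trace: np.ndarray, train_onset_ms: float,
                 baseline: Baseline, sample_rate: float,
                 stim_times_ms: np.ndarray | None = None,
                 criteria: OnsetCriteria = OnsetCriteria()) -> FDDIMetrics:
    """Full FDDI measurement of one averaged PC2 trace.

    Peak is the maximum of the baseline-subtracted mean after onset;
    half duration is the width of the contiguous region above half peak;
    charge is the trapezoidal integral from onset until the current falls
    back below threshold for ``end_sustained_ms`` (or the end of the trace).
    """
    onset = measure_onset_delay(mean_trace, train_onset_ms, baseline,
                                sample_rate, criteria)
    if onset is None:
        return FDDIMetrics("none", None, None, None, None, None)
    y = np.asarray(mean_trace, float) - baseline.mean
    dt = 1000.0 / sample_rate
    i_on = int(round((train_onset_ms + onset) / dt))
    thr = criteria.k * baseline.sd
    # end of the FDDI: first sustained drop below threshold after the onset
    n_end = max(1, int(round(criteria.end_sustained_ms / dt)))
    below = _sustained_above(-y[i_on:], -thr, n_end)  # y <= thr sustained
    i_end = i_on + int(below[0]) if below.size else y.size - 1
    seg = y[i_on:i_end + 1]
    ipk_rel = int(np.argmax(seg))
    peak = float(seg[ipk_rel])
    if peak < thr:
        raise ValueError("peak below detection threshold after onset")
    ipk = i_on + ipk_rel
    # AP index at which the peak occurs (last stimulus at or before the peak)
    peak_pulse = None
    if stim_times_ms is not None:
        t_pk = ipk * dt
        peak_pulse = int(np.searchsorted(np.asarray(stim_times_ms, float),
                                         t_pk, side="right") - 1)
    # half duration: contiguous region above peak/2 containing the peak
    half = peak / 2.0
    lo = ipk
    while lo > 0 and y[lo - 1] >= half:
        lo -= 1
    hi = ipk
    while hi < y.size - 1 and y[hi + 1] >= half:
        hi += 1
    half_duration = (hi - lo) * dt
    charge = float(np.trapezoid(seg, dx=dt))
    return FDDIMetrics("fddi", onset, peak, peak_pulse,
                       float(half_duration), charge)


def classify_pair_connection(sweeps: SweepSet,
                             baseline: Baseline | None = None,
                             mono_latency_ms: float = 4.0,
                             criteria: OnsetCriteria = OnsetCriteria()
                             ) -> FDDIMetrics:
    """Classify a paired PC-PC recording from its averaged PC2 trace.

    Monosynaptic: short-latency (<= ``mono_latency_ms``) inward deflections
    of at least ``k * sd`` following the individual APs of the train (the
    overlap of consecutive responses at 100 Hz is handled by subtracting,
    per AP, the trace value at the stimulus time). Disynaptic: a qualifying
    delayed outward onset (see :func:`measure_onset_delay`). A pair showing
    both carries classification ``'both'``.
    """
    mean = average_outward_current(sweeps)
    if baseline is None:
        # noise of the *averaged* trace sets the detection threshold
        end = float(sweeps.stim_times[0])
        baseline = estimate_baseline(mean, (max(0.0, end - 50.0), end),
                                     sweeps.sample_rate)
    y = mean - baseline.mean
    dt = 1000.0 / sweeps.sample_rate
    thr = criteria.k * baseline.sd
    n_mono = 0
    y_sm = _smooth_lowpass(y, sweeps.sample_rate)
    for t_stim in sweeps.stim_times:
        i0 = sweeps.sample_index(t_stim)
        i1 = min(sweeps.sample_index(t_stim + mono_latency_ms) + 1, y.size)
        if i1 - i0 < 3:
            continue
        # residual vs the window chord on the smoothed trace: removes the
        # summated tail of the previous EPSC and any slow disynaptic
        # component, leaving only the fast transient evoked by this AP
        seg = y_sm[i0:i1]
        chord = np.linspace(seg[0], seg[-1], seg.size)
        if np.min(seg - chord) <= -thr:  # inward = negative here
            n_mono += 1
    mono = n_mono >= max(2, sweeps.stim_times.size // 3)
    metrics = fddi_metrics(mean, float(sweeps.stim_times[0]), baseline,
                           sweeps.sample_rate, sweeps.stim_times, criteria)
    if metrics.classification == "fddi" and mono:
        metrics.classification = "both"
    elif metrics.classification == "none" and mono:
        metrics.classification = "monosynaptic"
    return metrics


def occurrence_test(counts: dict[str, tuple[int, int]]
                    ) -> tuple[dict[str, float], float, float]:
    """FDDI occurrence fractions per cohort and a Pearson chi-squared test.

    ``counts`` maps a cohort label to ``(n_with_fddi, n_pairs_total)``.
    Returns (occurrence fraction in % per cohort, chi2 statistic, p value);
    the test is Pearson's chi-squared without continuity correction.
    """
    labels = list(counts)
    table = np.array([[counts[g][0], counts[g][1] - counts[g][0]]
                      for g in labels])
    if np.any(table < 0):
        raise ValueError("counts must satisfy n_with <= n_total")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    occ = {g: 100.0 * counts[g][0] / counts[g][1] for g in labels}
    return occ, float(chi2), float(p)
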