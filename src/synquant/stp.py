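"""Short-term-plasticity train analysis.

During a presynaptic AP train the postsynaptic responses ride on the
decaying tails of their predecessors (temporal summation). Per-pulse
amplitudes are recovered by fitting the decay phase of each mean response
with one or two exponentials and subtracting the fitted residual at the
next peak; at 100 Hz, where the inter-pulse segments are too short to fit
individually, the decay of the *last* response is fitted and its time
constants propagated backward. The corrected amplitudes yield train ratios
(amp_n / amp_1, the paired-pulse ratio being n = 2), whose dependence on
interstimulus interval (PPF decay) and on time after a conditioning train
(recovery from facilitation) is fitted with exponential models; nested
models (one vs two components, shared vs per-group parameters) are selected
by the extra-sum-of-squares F test.

All exponential fits use variable projection: amplitudes enter linearly and
are solved exactly for any candidate time constants, so the nonlinear
search runs over the (log) time constants only, from multiple log-spaced
starts, with tau bounded to [1, 1e4] ms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .events import SweepSet, Baseline, baseline_for, _locate_peak, \
    _pulse_windows

__all__ = [
    "ExpFit", "TrainProfile", "fit_decay_model", "correct_temporal_summation",
    "train_profile", "fit_ppf_decay", "fit_recovery", "RecoveryFit",
    "PPFDecayFit",
]

TAU_BOUNDS = (1.0, 1.0e4)  # ms


@dataclass
class ExpFit:
    """One- or two-component exponential decay fit."""

    n_components: int
    amplitudes: tuple[float, ...]
    taus: tuple[float, ...]           # sorted fast -> slow for 2 components
    offset: float
    rss: float
    f_stat: float | None = None       # extra-SS F, 2 vs 1 components
    f_p: float | None = None
    flagged: bool = False             # tau at bound / non-decaying segment

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        out = np.full_like(t, self.offset, dtype=float)
        for a, tau in zip(self.amplitudes, self.taus):
            out += a * np.exp(-t / tau)
        return out

    def normalized_decay(self, t: np.ndarray) -> np.ndarray:
        """Decay shape normalized to 1 at t = 0 (offset excluded)."""
        total = sum(self.amplitudes)
        t = np.asarray(t, float)
        out = np.zeros_like(t, dtype=float)
        for a, tau in zip(self.amplitudes, self.taus):
            out += (a / total) * np.exp(-t / tau)
        return out


@dataclass
class TrainProfile:
    """Per-pulse amplitudes and ratios for one AP train."""

    corrected_amps: np.ndarray
    raw_amps: np.ndarray
    ratios: np.ndarray                # r_n = amp_n / amp_1, r_1 = 1
    ppr: float                        # r_2
    failure_percent: np.ndarray | None = None
    correction_mode: str = "per-pulse"


# ---------------------------------------------------------------------------
# exponential fitting by variable projection
# ---------------------------------------------------------------------------

def _linear_solve(t: np.ndarray, y: np.ndarray, taus: np.ndarray,
                  nonneg: bool = False) -> tuple[np.ndarray, float]:
    X = np.exp(-t[:, None] / taus[None, :])
    if nonneg:
        coef, _ = optimize.nnls(X, y)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)

def _fit_exp_sum(t: np.ndarray, y: np.ndarray, n_components: int,
                 nonneg: bool = False, n_starts: int = 6,
                 fixed_taus: dict[int, float] | None = None,
                 tau_bounds: tuple[float, float] = TAU_BOUNDS
                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares fit of sum_i a_i exp(-t/tau_i) via variable projection."""
    fixed_taus = fixed_taus or {}
    free = [i for i in range(n_components) if i not in fixed_taus]
    lo, hi = math.log(tau_bounds[0]), math.log(tau_bounds[1])
    span = max(t[-1] - t[0], 1.0)
    grid = np.log(np.clip(np.geomspace(span / 20, span * 20, n_starts),
                          *tau_bounds))

    def taus_from(theta: np.ndarray) -> np.ndarray:
        taus = np.empty(n_components)
        for j, i in enumerate(free):
            taus[i] = math.exp(min(max(theta[j], lo), hi))
        for i, v in fixed_taus.items():
            taus[i] = v
        return taus

    def rss_of(theta: np.ndarray) -> float:
        return _linear_solve(t, y, taus_from(theta), nonneg)[1]

    best = None
    if not free:
        starts: list[np.ndarray] = [np.empty(0)]
    elif len(free) == 1:
        starts = [np.array([g]) for g in grid]
    else:
        starts = [np.array([grid[i], grid[j]])
                  for i in range(len(grid)) for j in range(i + 1, len(grid))]
    for x0 in starts:
        if x0.size:
            res = optimize.minimize(rss_of, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-14,
                                             "maxiter": 600})
            cand = (res.fun, res.x)
        else:
            cand = (rss_of(x0), x0)
        if best is None or cand[0] < best[0]:
            best = cand
    taus = taus_from(best[1])
    coef, rss = _linear_solve(t, y, taus, nonneg)
    order = np.argsort(taus)
    return coef[order], taus[order], rss


def _extra_ss_f(rss_simple: float, df_simple: int, rss_complex: float,
                df_complex: int, scale: float) -> tuple[float, float]:
    """Extra-sum-of-squares F test of a nested pair of least-squares fits."""
    d_df = df_simple - df_complex
    if d_df <= 0 or df_complex <= 0:
        return np.nan, 1.0
    if rss_complex <= 1e-14 * scale:
        # both fits at numerical zero: the simpler model suffices
        if rss_simple <= 1e-14 * scale:
            return 0.0, 1.0
        return np.inf, 0.0
    f = ((rss_simple - rss_complex) / d_df) / (rss_complex / df_complex)
    p = float(stats.f.sf(f, d_df, df_complex))
    return float(f), p


def fit_decay_model(t_ms: np.ndarray, y: np.ndarray,
                    alpha: float = 0.05) -> ExpFit:
    """Fit a decay segment with 1 or 2 exponentials; select by F test.

    ``t_ms`` starts at the response peak (t = 0); the segment must contain
    at least 20 samples. The two-component model is retained only when the
    extra-sum-of-squares F test rejects the single exponential at ``alpha``.
    """
    t = np.asarray(t_ms, float)
    y = np.asarray(y, float)
    if t.size < 20:
        raise ValueError("decay segment needs at least 20 samples")
    scale = float(y @ y)
    if scale == 0.0:
        raise ValueError("all-zero decay segment")
    t = t - t[0]
    if t.size > 250:  # decimate long segments; an exact fit stays exact
        step = int(np.ceil(t.size / 250))
        idx = np.unique(np.r_[np.arange(0, t.size, step), t.size - 1])
        t, y = t[idx], y[idx]
        scale = float(y @ y)
    a1, tau1, rss1 = _fit_exp_sum(t, y, 1)
    fit1 = ExpFit(1, (float(a1[0]),), (float(tau1[0]),), 0.0, rss1)
    # noiseless single exponential: rss1 at machine zero, keep 1 component
    if rss1 <= 1e-14 * scale:
        fit1.f_stat, fit1.f_p = 0.0, 1.0
        fit1.flagged = _tau_at_bound(fit1.taus, fit1.amplitudes) or a1[0] <= 0
        return fit1
    a2, tau2, rss2 = _fit_exp_sum(t, y, 2)
    n = t.size
    f, p = _extra_ss_f(rss1, n - 2, rss2, n - 4, scale)
    if p < alpha and not math.isclose(tau2[0], tau2[1], rel_tol=1e-3):
        fit = ExpFit(2, tuple(map(float, a2)), tuple(map(float, tau2)),
                     0.0, rss2, f_stat=f, f_p=p)
    else:
        fit = fit1
        fit.f_stat, fit.f_p = f, p
    fit.flagged = _tau_at_bound(fit.taus, fit.amplitudes) or sum(fit.amplitudes) <= 0
    return fit


def _tau_at_bound(taus: tuple[float, ...],
                  amps: tuple[float, ...] | None = None) -> bool:
    # a negative-amplitude component is a rise remnant; only a *decay*
    # component pinned at a bound marks the fit as unreliable
    return any(math.isclose(x, b, rel_tol=1e-3)
               for x, a in zip(taus, amps or [1.0] * len(taus))
               for b in TAU_BOUNDS if a > 0)


# ---------------------------------------------------------------------------
# temporal-summation correction
# ---------------------------------------------------------------------------

def _window_mean(y: np.ndarray, center: int, half: int) -> float:
    j0, j1 = max(0, center - half), min(y.size, center + half + 1)
    return float(np.trapezoid(y[j0:j1]) / (j1 - j0 - 1))


def correct_temporal_summation(sweeps: SweepSet, baseline: Baseline | None = None,
                               mode: str = "per-pulse",
                               latency_window: tuple[float, float] = (1.0, 10.0),
                               peak_window_ms: float = 1.0,
                               alpha: float = 0.05) -> TrainProfile:
    """Per-pulse amplitudes of a mean train response, summation-corrected.

    The mean trace is measured per pulse as the 1-ms window around the peak
    after each stimulus (baseline-subtracted). In ``per-pulse`` mode the
    decay of each response (peak to next stimulus) is fitted and the fitted
    residual, averaged over the next pulse's measurement window, is
    subtracted from the next raw amplitude. In ``last-pulse`` mode (used
    for 100-Hz trains, and as automatic fallback when an inter-pulse
    segment is unfittable) only the final response's decay is fitted and
    its normalized time constants propagate every residual backward from
    the observed compound peak values.
    """
    if baseline is None:
        baseline = baseline_for(sweeps)
    mean = sweeps.mean_trace()
    y = sweeps.polarity * (mean - baseline.mean)
    sr = sweeps.sample_rate
    dt = 1000.0 / sr
    half = max(1, int(round(peak_window_ms / 2.0 * sr / 1000.0)))
    windows = _pulse_windows(sweeps, latency_window)
    n_pulses = len(windows)
    # adjacent latency windows may overlap the next stimulus at 100 Hz;
    # clip each search window at the next stimulus time
    peaks = []
    for j, (i0, i1) in enumerate(windows):
        if j + 1 < n_pulses:
            i1 = min(i1, sweeps.sample_index(sweeps.stim_times[j + 1]))
        peaks.append(_locate_peak(y, sr, (i0, i1), +1))
    raw = np.array([_window_mean(y, pk, half) for pk in peaks])
    compound = raw.copy()  # observed (summed) window amplitudes
    corrected = raw.copy()
    mode_used = mode

    def segment(j: int) -> tuple[np.ndarray, np.ndarray]:
        s0 = peaks[j]
        s1 = (sweeps.sample_index(sweeps.stim_times[j + 1])
              if j + 1 < n_pulses else y.size)
        return np.arange(s0, s1) * dt, y[s0:s1]

    if mode == "per-pulse":
        fits: list[ExpFit | None] = []
        ok = True
        for j in range(n_pulses - 1):
            t_seg, y_seg = segment(j)
            try:
                fit = fit_decay_model(t_seg - t_seg[0], y_seg, alpha=alpha)
                if fit.flagged:
                    raise ValueError("non-decaying segment")
                fits.append(fit)
            except ValueError:
                ok = False
                break
        if ok:
            for j in range(n_pulses - 1):
                w = (np.arange(peaks[j + 1] - half, peaks[j + 1] + half + 1)
                     * dt - peaks[j] * dt)
                w = w[(w >= 0)]
                resid = (float(np.trapezoid(fits[j](w)) / (w.size - 1))
                         if w.size > 1 else 0.0)
                corrected[j + 1] = compound[j + 1] - resid
        else:
            warnings.warn("per-pulse decay unfittable; falling back to "
                          "last-pulse temporal-summation correction")
            mode_used = "last-pulse"
    if mode_used == "last-pulse" or mode == "last-pulse":
        mode_used = "last-pulse"
        t_seg, y_seg = segment(n_pulses - 1)
        last_fit = fit_decay_model(t_seg - t_seg[0], y_seg, alpha=alpha)
        corrected = compound.copy()
        for j in range(n_pulses - 1):
            w = (np.arange(peaks[j + 1] - half, peaks[j + 1] + half + 1)
                 * dt - peaks[j] * dt)
            w = w[w >= 0]
            d = (float(np.trapezoid(last_fit.normalized_decay(w)) / (w.size - 1))
                 if w.size > 1 else 0.0)
            corrected[j + 1] = compound[j + 1] - compound[j] * d
    ratios = corrected / corrected[0] if corrected[0] > 0 else \
        np.full(n_pulses, np.nan)
    return TrainProfile(corrected_amps=corrected, raw_amps=raw, ratios=ratios,
                        ppr=float(ratios[1]) if n_pulses > 1 else np.nan,
                        correction_mode=mode_used)


def train_profile(corrected_amps: np.ndarray,
                  failures_per_pulse: np.ndarray | None = None) -> TrainProfile:
    """Ratios r_n = amp_n / amp_1 and the paired-pulse ratio from amplitudes."""
    amps = np.asarray(corrected_amps, float)
    if amps.size < 1 or amps[0] <= 0:
        raise ValueError("amp_1 must be positive to form train ratios")
    ratios = amps / amps[0]
    fp = None
    if failures_per_pulse is not None:
        fp = np.asarray(failures_per_pulse, float)
    return TrainProfile(corrected_amps=amps, raw_amps=amps, ratios=ratios,
                        ppr=float(ratios[1]) if amps.size > 1 else np.nan,
                        failure_percent=fp)


# ---------------------------------------------------------------------------
# PPF decay: shared vs separate fits across groups
# ---------------------------------------------------------------------------

@dataclass
class PPFDecayFit:
    """PPR(dt) = 1 + A exp(-dt/tau), fitted per group and shared."""

    shared_amp: float
    shared_tau: float
    group_fits: dict[str, tuple[float, float]]   # label -> (A, tau)
    f_stat: float
    f_p: float
    shared_selected: bool
    rss_shared: float
    rss_separate: float

    def shared_model(self, dt: np.ndarray) -> np.ndarray:
        return 1.0 + self.shared_amp * np.exp(-np.asarray(dt, float)
                                              / self.shared_tau)


def _fit_ppf_one(isi: np.ndarray, ppr: np.ndarray) -> tuple[float, float, float]:
    a, tau, rss = _fit_exp_sum(isi, ppr - 1.0, 1, nonneg=True)
    return float(a[0]), float(tau[0]), rss


def fit_ppf_decay(groups: dict[str, tuple[np.ndarray, np.ndarray]],
                  alpha: float = 0.05) -> PPFDecayFit:
    """Fit paired-pulse-ratio decay vs ISI, shared across groups or separate.

    ``groups`` maps a label to ``(isi_ms, ppr)`` arrays (>=4 ISIs each, >=2
    groups). The facilitation decays to an asymptote of 1 (no facilitation
    at long intervals). The extra-sum-of-squares F test compares the shared
    two-parameter fit against per-group parameters.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    prepared = {}
    for label, (isi, ppr) in groups.items():
        isi = np.asarray(isi, float)
        ppr = np.asarray(ppr, float)
        if np.unique(isi).size < 4:
            raise ValueError(f"group {label!r} needs >=4 distinct ISIs")
        if np.any(ppr < 0):
            raise ValueError("PPR cannot be negative")
        prepared[label] = (isi, ppr)
    all_isi = np.concatenate([v[0] for v in prepared.values()])
    all_ppr = np.concatenate([v[1] for v in prepared.values()])
    a_sh, tau_sh, rss_sh = _fit_ppf_one(all_isi, all_ppr)
    group_fits, rss_sep = {}, 0.0
    for label, (isi, ppr) in prepared.items():
        a, tau, rss = _fit_ppf_one(isi, ppr)
        group_fits[label] = (a, tau)
        rss_sep += rss
    n = all_isi.size
    k_sep = 2 * len(prepared)
    f, p = _extra_ss_f(rss_sh, n - 2, rss_sep, n - k_sep,
                       float(all_ppr @ all_ppr))
    return PPFDecayFit(shared_amp=a_sh, shared_tau=tau_sh,
                       group_fits=group_fits, f_stat=f, f_p=p,
                       shared_selected=p >= alpha, rss_shared=rss_sh,
                       rss_separate=rss_sep)


# ---------------------------------------------------------------------------
# recovery from facilitation after a 100-Hz train
# ---------------------------------------------------------------------------

@dataclass
class RecoveryFit:
    """amp(dt) = 1 + B [A_f exp(-dt/tau_f) + (1-A_f) exp(-dt/tau_s)]."""

    amplitude: float       # B, total facilitation above the baseline response
    frac_fast: float       # A_f
    tau_fast: float
    tau_slow: float
    rss: float
    constrained: bool

    def __call__(self, dt: np.ndarray) -> np.ndarray:
        dt = np.asarray(dt, float)
        return 1.0 + self.amplitude * (
            self.frac_fast * np.exp(-dt / self.tau_fast)
            + (1.0 - self.frac_fast) * np.exp(-dt / self.tau_slow))

    def recovery_fraction(self, t: np.ndarray | float) -> np.ndarray | float:
        """Fraction of the facilitation that has decayed away by time t."""
        t = np.asarray(t, float)
        out = 1.0 - (self.frac_fast * np.exp(-t / self.tau_fast)
                     + (1.0 - self.frac_fast) * np.exp(-t / self.tau_slow))
        return float(out) if out.ndim == 0 else out


def fit_recovery(delays_ms: np.ndarray, amps: np.ndarray,
                 constrain_tau_fast: float | None = None) -> RecoveryFit:
    """Biexponential fit of post-train response amplitudes vs delay.

    ``amps`` are normalized to the pre-train baseline response (-> 1 at
    infinite delay). With ``constrain_tau_fast`` the fast time constant is
    fixed exactly (the slow one and both amplitude terms remain free),
    mirroring the constrained fit used when PPF decay pins the fast
    component.
    """
    delays = np.asarray(delays_ms, float)
    amps = np.asarray(amps, float)
    if np.any(np.diff(delays) <= 0) or np.any(delays <= 0):
        raise ValueError("delays must be positive and increasing")
    if np.any(amps < 0):
        raise ValueError("amplitudes must be non-negative")
    n_free = 3 if constrain_tau_fast is not None else 4
    if delays.size < n_free + 1:
        raise ValueError("fewer points than free parameters")
    if constrain_tau_fast is not None:
        # the free (slow) component is bounded below by the fixed fast tau
        coef, taus, rss = _fit_exp_sum(
            delays, amps - 1.0, 2, nonneg=True,
            fixed_taus={0: float(constrain_tau_fast)},
            tau_bounds=(float(constrain_tau_fast), TAU_BOUNDS[1]))
    else:
        coef, taus, rss = _fit_exp_sum(delays, amps - 1.0, 2, nonneg=True)
    b_fast, b_slow = float(coef[0]), float(coef[1])
    amplitude = b_fast + b_slow
    frac_fast = b_fast / amplitude if amplitude > 0 else 0.0
    return RecoveryFit(amplitude=amplitude, frac_fast=frac_fast,
                       tau_fast=float(taus[0]), tau_slow=float(taus[1]),
                       rss=rss, constrained=constrain_tau_fast is not None)
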