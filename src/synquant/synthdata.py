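"""Synthetic paired-recording generator with known ground truth.

The generative model mirrors the assumptions of the downstream analysis:

* **Release** — a synapse has ``n_sites`` independent release sites, each
  releasing on a presynaptic AP with probability ``p_k`` (binomial model),
  contributing one quantum of postsynaptic amplitude ``q`` (lognormal
  variability with a given CV).
* **Facilitation** — residual-calcium style: a facilitation factor ``F``
  (``F >= 1``) jumps by ``facil_increment`` after every AP and relaxes
  exponentially back to 1 with ``tau_facil``; the effective probability at
  pulse *k* is ``p_k = min(1, p0 * F_k)`` with ``F_1 = 1``.
* **Depression** — per-site binary occupancy: a site that releases is empty
  until it refills, with probability ``1 - exp(-dt/tau_recovery)`` per
  inter-pulse interval.
* **Rendering** — each released packet is convolved with a
  difference-of-exponentials kernel normalized to unit peak (so ``q`` is the
  peak amplitude by construction), with per-trial latency jitter, Gaussian
  baseline noise, and an optional slow multiplicative rundown of ``q``.
* **Disynaptic circuit** — PC1 fires a 100-Hz train; a facilitating
  excitatory synapse drives a leaky-integrator SOM interneuron whose
  threshold crossings emit spikes; each spike produces, after a conduction
  delay, an outward IPSC in the voltage-clamped PC2.

Every stochastic routine takes an explicit seed or Generator, and every
simulated :class:`~synquant.events.SweepSet` is returned together with a
:class:`GroundTruth` recording the generating parameters and the per-sweep,
per-pulse release counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .events import SweepSet

__all__ = [
    "ReleaseParams", "STPParams", "KernelParams", "NoiseParams", "Protocol",
    "CircuitParams", "GroundTruth",
    "facilitation_factors", "effective_release_probabilities",
    "expected_pulse_amplitudes", "psp_kernel", "expected_mean_trace",
    "simulate_connection_sweeps", "sample_connection_summary",
    "simulate_fddi_experiment", "simulate_ppf_series",
    "simulate_recovery_series", "make_cohort", "COHORT_PRESETS",
]


# ---------------------------------------------------------------------------
# parameter objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReleaseParams:
    """Binomial release model: N sites, baseline probability p0, quantum q."""

    n_sites: int
    p0: float
    q: float
    quantal_cv: float = 0.0

    def __post_init__(self) -> None:
        if not (self.n_sites >= 1 and float(self.n_sites).is_integer()):
            raise ValueError("n_sites must be an integer >= 1")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if not self.q > 0:
            raise ValueError("q must be positive")
        if self.quantal_cv < 0:
            raise ValueError("quantal_cv must be >= 0")
        for v in (self.p0, self.q, self.quantal_cv):
            if not math.isfinite(v):
                raise ValueError("release parameters must be finite")


@dataclass(frozen=True)
class STPParams:
    """Facilitation increment/decay and per-site depletion recovery."""

    facil_increment: float = 0.0
    tau_facil: float = 54.0
    depletion_enabled: bool = False
    tau_recovery: float = 500.0

    def __post_init__(self) -> None:
        if self.facil_increment < 0:
            raise ValueError("facil_increment must be >= 0")
        if self.tau_facil <= 0 or self.tau_recovery <= 0:
            raise ValueError("time constants must be positive")

    @classmethod
    def none(cls) -> "STPParams":
        return cls(facil_increment=0.0, depletion_enabled=False)


@dataclass(frozen=True)
class KernelParams:
    """Difference-of-exponentials PSP/PSC kernel, unit peak, with latency."""

    latency: float = 1.5
    jitter_sd: float = 0.0
    rise_tau: float = 0.5
    decay_tau: float = 20.0

    def __post_init__(self) -> None:
        if self.latency < 0 or self.jitter_sd < 0:
            raise ValueError("latency and jitter_sd must be >= 0")
        if self.rise_tau <= 0 or self.decay_tau <= self.rise_tau:
            raise ValueError("need 0 < rise_tau < decay_tau")


@dataclass(frozen=True)
class NoiseParams:
    """Gaussian baseline noise and linear rundown of q (fraction per minute)."""

    baseline_sd: float = 0.0
    rundown_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.rundown_rate < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol for one sweep set."""

    n_pulses: int = 1
    freq: float = 25.0
    inter_trial: float = 40.0
    n_sweeps: int = 30
    sample_rate: float = 10_000.0
    pre_window: float = 60.0
    clamp_mode: str = "current"
    tail_ms: float | None = None
    stim_override_ms: tuple[float, ...] | None = None
    isi_list: tuple[float, ...] | None = None
    recovery_delays: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_pulses < 1 or self.n_sweeps < 1:
            raise ValueError("n_pulses and n_sweeps must be >= 1")
        if self.freq <= 0 or self.sample_rate <= 0:
            raise ValueError("freq and sample_rate must be positive")

    def stim_times_ms(self) -> np.ndarray:
        if self.stim_override_ms is not None:
            return self.pre_window + np.asarray(self.stim_override_ms, float)
        return self.pre_window + np.arange(self.n_pulses) * 1000.0 / self.freq

    def duration_ms(self, kernel: KernelParams) -> float:
        tail = self.tail_ms
        if tail is None:
            tail = max(50.0, kernel.latency + 8.0 * kernel.decay_tau + 10.0)
        return float(self.stim_times_ms()[-1] + tail)


@dataclass(frozen=True)
class CircuitParams:
    """PC1 -> SOM interneuron -> PC2 disynaptic inhibition circuit.

    The SOM membrane is a leaky integrator of unitary EPSPs (the EPSP kernel
    decay doubles as the membrane time constant); each threshold crossing
    emits a spike, clears the accumulated depolarization, and after
    ``som_to_pc2_delay`` produces an outward IPSC of ``ipsc_amp`` pA in PC2.
    """

    pc_to_som_release: ReleaseParams = ReleaseParams(n_sites=30, p0=0.05,
                                                     q=0.18)
    pc_to_som_stp: STPParams = STPParams(facil_increment=4.8, tau_facil=54.0,
                                         depletion_enabled=True,
                                         tau_recovery=5.0)
    epsp_kernel: KernelParams = KernelParams(latency=1.5, jitter_sd=0.2,
                                             rise_tau=1.0, decay_tau=30.0)
    som_threshold: float = 7.4       # mV above rest
    som_refractory: float = 5.0      # ms
    som_to_pc2_delay: float = 2.0    # ms, SOM spike -> IPSC onset
    ipsc_amp: float = 6.5            # pA, outward-positive at -40 mV
    ipsc_cv: float = 0.2
    ipsc_kernel: KernelParams = KernelParams(latency=0.0, jitter_sd=0.0,
                                             rise_tau=2.0, decay_tau=45.0)
    noise: NoiseParams = NoiseParams(baseline_sd=1.5)
    # mean-field drive: the SOM cell receives the expected per-pulse EPSP
    # amplitudes (infinite-site limit) rather than a binomial sample, so
    # its recruitment time is set by the synapse's mean dynamics
    deterministic_som: bool = True

    def __post_init__(self) -> None:
        if self.som_threshold <= 0:
            raise ValueError("som_threshold must exceed the resting level")
        if self.ipsc_amp <= 0:
            raise ValueError("ipsc_amp must be positive")
        if self.som_to_pc2_delay < 0:
            raise ValueError("delays must be >= 0")


@dataclass
class GroundTruth:
    """Hidden generating state stored alongside every simulated sweep set."""

    params: dict
    p_eff: np.ndarray                 # effective p per pulse
    release_counts: np.ndarray        # (n_sweeps, n_pulses) quanta released
    quantal_sums: np.ndarray          # (n_sweeps, n_pulses) summed amplitude
    expected_amps: np.ndarray         # closed-form E[amplitude] per pulse
    som_spike_times: list | None = None   # FDDI: per-sweep spike times, ms
    onset_ms: float | None = None         # FDDI: first spike + delay - train onset
    seed: int | None = None


# ---------------------------------------------------------------------------
# closed-form pieces
# ---------------------------------------------------------------------------

def facilitation_factors(stp: STPParams, isi_ms: np.ndarray | float,
                         n_pulses: int) -> np.ndarray:
    """F_k for each pulse: F_1 = 1; jump by a_F after each AP, relax to 1."""
    isi = np.broadcast_to(np.asarray(isi_ms, float), (max(n_pulses - 1, 0),))
    F = np.empty(n_pulses)
    F[0] = 1.0
    for k in range(1, n_pulses):
        decay = math.exp(-isi[k - 1] / stp.tau_facil)
        F[k] = 1.0 + (F[k - 1] + stp.facil_increment - 1.0) * decay
    return F


def effective_release_probabilities(release: ReleaseParams, stp: STPParams,
                                    isi_ms: np.ndarray | float,
                                    n_pulses: int) -> np.ndarray:
    return np.minimum(1.0, release.p0 * facilitation_factors(stp, isi_ms, n_pulses))


def expected_pulse_amplitudes(release: ReleaseParams, stp: STPParams,
                              isi_ms: np.ndarray | float,
                              n_pulses: int) -> np.ndarray:
    """Exact expected summed quantal amplitude per pulse, N * o_k * p_k * q.

    ``o_k`` is the per-site occupancy probability, computed recursively:
    a site empties when it releases and refills between pulses with
    probability ``1 - exp(-isi/tau_recovery)``.
    """
    p = effective_release_probabilities(release, stp, isi_ms, n_pulses)
    isi = np.broadcast_to(np.asarray(isi_ms, float), (max(n_pulses - 1, 0),))
    o = np.empty(n_pulses)
    o[0] = 1.0
    for k in range(1, n_pulses):
        occupied = o[k - 1] * (1.0 - p[k - 1])
        if stp.depletion_enabled:
            refill = 1.0 - math.exp(-isi[k - 1] / stp.tau_recovery)
            o[k] = occupied + (1.0 - occupied) * refill
        else:
            o[k] = 1.0
    return release.n_sites * o * p * release.q


def psp_kernel(kernel: KernelParams, t_ms: np.ndarray) -> np.ndarray:
    """Unit-peak difference of exponentials; zero before the latency."""
    t = np.asarray(t_ms, float) - kernel.latency
    tr, td = kernel.rise_tau, kernel.decay_tau
    t_peak = math.log(td / tr) * tr * td / (td - tr)
    peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    out = np.where(t > 0, (np.exp(-np.maximum(t, 0) / td)
                           - np.exp(-np.maximum(t, 0) / tr)) / peak, 0.0)
    return out


# ---------------------------------------------------------------------------
# core sampling
# ---------------------------------------------------------------------------

def _sample_release(release: ReleaseParams, stp: STPParams,
                    isi_ms: np.ndarray, n_pulses: int, n_sweeps: int,
                    rng: np.random.Generator,
                    q_scale: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample per-sweep per-pulse release counts and summed quantal amplitudes."""
    p = effective_release_probabilities(release, stp, isi_ms, n_pulses)
    N = release.n_sites
    counts = np.zeros((n_sweeps, n_pulses), dtype=int)
    sums = np.zeros((n_sweeps, n_pulses))
    occupied = np.ones((n_sweeps, N), dtype=bool)
    if q_scale is None:
        q_scale = np.ones(n_sweeps)
    if release.quantal_cv > 0:
        sigma2 = math.log(1.0 + release.quantal_cv ** 2)
        mu = math.log(release.q) - sigma2 / 2.0
    for k in range(n_pulses):
        releasing = occupied & (rng.random((n_sweeps, N)) < p[k])
        counts[:, k] = releasing.sum(axis=1)
        if release.quantal_cv > 0:
            amps = np.where(releasing,
                            rng.lognormal(mu, math.sqrt(sigma2), (n_sweeps, N)),
                            0.0)
            sums[:, k] = amps.sum(axis=1) * q_scale
        else:
            sums[:, k] = counts[:, k] * release.q * q_scale
        if stp.depletion_enabled:
            occupied = occupied & ~releasing
            if k < n_pulses - 1:
                refill = 1.0 - math.exp(-isi_ms[k] / stp.tau_recovery)
                occupied |= rng.random((n_sweeps, N)) < refill
        # without depletion every site stays occupied
    return counts, sums, p


def _render_traces(quantal_sums: np.ndarray, stim_ms: np.ndarray,
                   kernel: KernelParams, noise: NoiseParams,
                   sample_rate: float, n_samples: int,
                   rng: np.random.Generator) -> np.ndarray:
    n_sweeps, n_pulses = quantal_sums.shape
    dt = 1000.0 / sample_rate
    span = kernel.latency + 3 * kernel.jitter_sd + 10.0 * kernel.decay_tau
    klen = int(span / dt) + 1
    traces = np.zeros((n_sweeps, n_samples))
    t_rel = np.arange(klen) * dt
    if kernel.jitter_sd > 0:
        jit = rng.normal(0.0, kernel.jitter_sd, (n_sweeps, n_pulses))
    else:
        jit = np.zeros((n_sweeps, n_pulses))
    for s in range(n_sweeps):
        for k in range(n_pulses):
            a = quantal_sums[s, k]
            if a == 0.0:
                continue
            i0 = int(round(stim_ms[k] / dt))
            frac = stim_ms[k] - i0 * dt
            kern = psp_kernel(
                KernelParams(latency=max(0.0, kernel.latency + jit[s, k]),
                             jitter_sd=0.0, rise_tau=kernel.rise_tau,
                             decay_tau=kernel.decay_tau), t_rel - frac)
            i1 = min(i0 + klen, n_samples)
            if i1 - i0 < klen * 0.5 and i1 == n_samples:
                raise ValueError("response overruns the sweep; extend tail_ms")
            traces[s, i0:i1] += a * kern[: i1 - i0]
    if noise.baseline_sd > 0:
        traces += rng.normal(0.0, noise.baseline_sd, traces.shape)
    return traces


def expected_mean_trace(release: ReleaseParams, stp: STPParams,
                        kernel: KernelParams, protocol: Protocol) -> SweepSet:
    """Deterministic, noiseless expected mean trace (one 'sweep').

    Renders the closed-form expected per-pulse amplitudes through the same
    kernel as the stochastic path; serves as the infinite-sweep oracle.
    """
    stim = protocol.stim_times_ms()
    isi = np.diff(stim)
    amps = expected_pulse_amplitudes(release, stp,
                                     isi if isi.size else 1.0, stim.size)
    n_samples = int(protocol.duration_ms(kernel) * protocol.sample_rate / 1000.0)
    rng = np.random.default_rng(0)  # unused: no noise, no jitter
    det_kernel = KernelParams(latency=kernel.latency, jitter_sd=0.0,
                              rise_tau=kernel.rise_tau,
                              decay_tau=kernel.decay_tau)
    traces = _render_traces(amps[None, :], stim, det_kernel, NoiseParams(),
                            protocol.sample_rate, n_samples, rng)
    return SweepSet(traces=traces, sample_rate=protocol.sample_rate,
                    stim_times=stim, sweep_timestamps=np.zeros(1),
                    clamp_mode=protocol.clamp_mode, polarity=+1,
                    metadata={"kind": "expected_mean"})


# ---------------------------------------------------------------------------
# public simulation entry points
# ---------------------------------------------------------------------------

def simulate_connection_sweeps(release: ReleaseParams, stp: STPParams,
                               kernel: KernelParams, noise: NoiseParams,
                               protocol: Protocol,
                               seed: int | np.random.Generator
                               ) -> tuple[SweepSet, GroundTruth]:
    """Simulate one paired connection under a stimulation protocol."""
    rng = np.random.default_rng(seed)
    stim = protocol.stim_times_ms()
    isi = np.diff(stim) if stim.size > 1 else np.asarray([1.0])
    timestamps = np.arange(protocol.n_sweeps) * protocol.inter_trial
    q_scale = np.clip(1.0 - noise.rundown_rate * timestamps / 60.0, 0.0, None)
    counts, sums, p = _sample_release(release, stp, isi, stim.size,
                                      protocol.n_sweeps, rng, q_scale)
    n_samples = int(protocol.duration_ms(kernel) * protocol.sample_rate / 1000.0)
    traces = _render_traces(sums, stim, kernel, noise, protocol.sample_rate,
                            n_samples, rng)
    sweeps = SweepSet(traces=traces, sample_rate=protocol.sample_rate,
                      stim_times=stim, sweep_timestamps=timestamps,
                      clamp_mode=protocol.clamp_mode, polarity=+1,
                      metadata={"kind": "connection"})
    gt = GroundTruth(params={"release": asdict(release), "stp": asdict(stp),
                             "kernel": asdict(kernel), "noise": asdict(noise),
                             "protocol": asdict(protocol)},
                     p_eff=p, release_counts=counts, quantal_sums=sums,
                     expected_amps=expected_pulse_amplitudes(
                         release, stp, isi, stim.size),
                     seed=seed if isinstance(seed, int) else None)
    return sweeps, gt


def sample_connection_summary(release: ReleaseParams, stp: STPParams,
                              n_sweeps: int, rng: np.random.Generator,
                              isi_ms: float = 40.0, n_pulses: int = 1
                              ) -> tuple[float, float, np.ndarray]:
    """Summary-level draw from the same release model, without rendering.

    Returns (mean first-pulse amplitude, first-pulse failure fraction,
    release counts). Identical generative core as the trace path; used for
    large replicate cohorts where only per-connection summaries are needed.
    """
    counts, sums, _ = _sample_release(release, stp,
                                      np.full(max(n_pulses - 1, 1), isi_ms),
                                      n_pulses, n_sweeps, rng)
    return (float(sums[:, 0].mean()), float((counts[:, 0] == 0).mean()), counts)


def simulate_ppf_series(release: ReleaseParams, stp: STPParams,
                        kernel: KernelParams, noise: NoiseParams,
                        protocol: Protocol, seed: int
                        ) -> dict[float, tuple[SweepSet, GroundTruth]]:
    """Paired-pulse protocol across the ISIs in ``protocol.isi_list``."""
    if not protocol.isi_list:
        raise ValueError("protocol.isi_list is required for a PPF series")
    rng = np.random.default_rng(seed)
    out = {}
    for isi in protocol.isi_list:
        p = Protocol(n_pulses=2, freq=1000.0 / isi,
                     inter_trial=protocol.inter_trial,
                     n_sweeps=protocol.n_sweeps,
                     sample_rate=protocol.sample_rate,
                     pre_window=protocol.pre_window,
                     clamp_mode=protocol.clamp_mode, tail_ms=protocol.tail_ms)
        out[float(isi)] = simulate_connection_sweeps(release, stp, kernel,
                                                     noise, p, rng)
    return out


def simulate_recovery_series(release: ReleaseParams, stp: STPParams,
                             kernel: KernelParams, noise: NoiseParams,
                             protocol: Protocol, seed: int,
                             train_pulses: int = 5, train_freq: float = 100.0
                             ) -> dict[float, tuple[SweepSet, GroundTruth]]:
    """A conditioning train plus one test pulse at each recovery delay."""
    if not protocol.recovery_delays:
        raise ValueError("protocol.recovery_delays is required")
    rng = np.random.default_rng(seed)
    train = np.arange(train_pulses) * 1000.0 / train_freq
    out = {}
    for delay in protocol.recovery_delays:
        stim = tuple(train) + (train[-1] + delay,)
        p = Protocol(n_pulses=len(stim), freq=train_freq,
                     inter_trial=protocol.inter_trial,
                     n_sweeps=protocol.n_sweeps,
                     sample_rate=protocol.sample_rate,
                     pre_window=protocol.pre_window,
                     clamp_mode=protocol.clamp_mode, tail_ms=protocol.tail_ms,
                     stim_override_ms=stim)
        out[float(delay)] = simulate_connection_sweeps(release, stp, kernel,
                                                       noise, p, rng)
    return out


# ---------------------------------------------------------------------------
# disynaptic circuit
# ---------------------------------------------------------------------------

def _som_spikes(event_times: np.ndarray, event_amps: np.ndarray,
                kernel: KernelParams, threshold: float, refractory: float,
                t_grid: np.ndarray) -> list[float]:
    """Threshold crossings of a leaky integrator of EPSP kernels.

    The membrane depolarization is the superposition of unit-peak kernels
    scaled by the released quantal amplitudes; a spike clears all
    contributions from events at or before the spike time (reset) and
    imposes an absolute refractory period.
    """
    spikes: list[float] = []
    active = list(range(len(event_times)))
    start = 0
    while True:
        v = np.zeros_like(t_grid[start:])
        for i in active:
            v += event_amps[i] * psp_kernel(kernel, t_grid[start:] - event_times[i])
        above = np.nonzero(v >= threshold)[0]
        if above.size == 0:
            return spikes
        idx = start + above[0]
        t_spike = t_grid[idx]
        spikes.append(float(t_spike))
        active = [i for i in active if event_times[i] > t_spike]
        dt = t_grid[1] - t_grid[0]
        start = idx + max(1, int(refractory / dt))
        if start >= t_grid.size or not active:
            return spikes


def simulate_fddi_experiment(circuit: CircuitParams, protocol: Protocol,
                             seed: int | np.random.Generator
                             ) -> tuple[SweepSet, GroundTruth]:
    """Simulate PC2 voltage-clamp sweeps during a 100-Hz 10-AP train in PC1."""
    if protocol.n_sweeps < 1:
        raise ValueError("need at least one sweep")
    rng = np.random.default_rng(seed)
    stim = protocol.stim_times_ms()
    isi = np.diff(stim) if stim.size > 1 else np.asarray([1.0])
    rel, stp = circuit.pc_to_som_release, circuit.pc_to_som_stp
    counts, sums, p = _sample_release(rel, stp, isi, stim.size,
                                      protocol.n_sweeps, rng)
    if circuit.deterministic_som:
        sums = np.tile(expected_pulse_amplitudes(rel, stp, isi, stim.size),
                       (protocol.n_sweeps, 1))
    dur = protocol.duration_ms(circuit.ipsc_kernel)
    dur = max(dur, stim[-1] + 300.0)
    n_samples = int(dur * protocol.sample_rate / 1000.0)
    dt = 1000.0 / protocol.sample_rate
    t_grid = np.arange(n_samples) * dt
    ek = circuit.epsp_kernel
    traces = np.zeros((protocol.n_sweeps, n_samples))
    spike_times: list[list[float]] = []
    if ek.jitter_sd > 0:
        jitter = rng.normal(0.0, ek.jitter_sd, (protocol.n_sweeps, stim.size))
    else:
        jitter = np.zeros((protocol.n_sweeps, stim.size))
    for s in range(protocol.n_sweeps):
        ev_t = stim + ek.latency + jitter[s]
        kern = KernelParams(latency=0.0, jitter_sd=0.0, rise_tau=ek.rise_tau,
                            decay_tau=ek.decay_tau)
        spikes = _som_spikes(ev_t, sums[s], kern, circuit.som_threshold,
                             circuit.som_refractory, t_grid)
        spike_times.append(spikes)
        for t_sp in spikes:
            amp = circuit.ipsc_amp
            if circuit.ipsc_cv > 0:
                sigma2 = math.log(1.0 + circuit.ipsc_cv ** 2)
                amp = rng.lognormal(math.log(amp) - sigma2 / 2.0,
                                    math.sqrt(sigma2))
            t0 = t_sp + circuit.som_to_pc2_delay
            traces[s] += amp * psp_kernel(circuit.ipsc_kernel, t_grid - t0)
    if circuit.noise.baseline_sd > 0:
        traces += rng.normal(0.0, circuit.noise.baseline_sd, traces.shape)
    sweeps = SweepSet(traces=traces, sample_rate=protocol.sample_rate,
                      stim_times=stim,
                      sweep_timestamps=np.arange(protocol.n_sweeps)
                      * protocol.inter_trial,
                      clamp_mode="voltage", polarity=+1,
                      metadata={"kind": "fddi"})
    firsts = [sp[0] for sp in spike_times if sp]
    onset = (float(np.median(firsts)) + circuit.som_to_pc2_delay - stim[0]
             if firsts else None)
    gt = GroundTruth(params={"circuit": asdict(circuit),
                             "protocol": asdict(protocol)},
                     p_eff=p, release_counts=counts, quantal_sums=sums,
                     expected_amps=expected_pulse_amplitudes(rel, stp, isi,
                                                             stim.size),
                     som_spike_times=spike_times, onset_ms=onset,
                     seed=seed if isinstance(seed, int) else None)
    return sweeps, gt


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

# Per-connection parameter ranges. PC->SOM is a low-p facilitating synapse
# (q fixed across connections so the failure-vs-amplitude relation is a
# shared line); SOM->PC is high-p and mildly depressing; PC->PC is
# intermediate. The FHM1 genotype scales p0 only (gain-of-function of
# release probability), never q.
COHORT_PRESETS: dict[str, dict] = {
    "PC-SOM": {
        "q": 0.926, "quantal_cv": 0.3,
        "n_sites_range": (1, 5), "p0_range": (0.02, 0.08),
        "fhm1_p_scale": 2.14,
        "stp": STPParams(facil_increment=4.8, tau_facil=54.0),
        "kernel": KernelParams(latency=1.5, jitter_sd=0.15, rise_tau=1.0,
                               decay_tau=30.0),
        "noise_sd": 0.02, "units": "mV",
    },
    "SOM-PC": {
        "q": 30.0, "quantal_cv": 0.3,
        "n_sites_range": (4, 6), "p0_range": (0.3, 0.5),
        "fhm1_p_scale": 1.0,
        "stp": STPParams(depletion_enabled=True, tau_recovery=25.0),
        "kernel": KernelParams(latency=1.2, jitter_sd=0.1, rise_tau=0.8,
                               decay_tau=12.0),
        "noise_sd": 2.0, "units": "pA",
    },
    "PC-PC": {
        "q": 0.3, "quantal_cv": 0.3,
        "n_sites_range": (2, 6), "p0_range": (0.08, 0.2),
        "fhm1_p_scale": 2.0,
        "stp": STPParams(facil_increment=1.0, tau_facil=80.0,
                         depletion_enabled=True, tau_recovery=600.0),
        "kernel": KernelParams(latency=1.5, jitter_sd=0.15, rise_tau=1.0,
                               decay_tau=25.0),
        "noise_sd": 0.02, "units": "mV",
    },
}

# Circuit presets: FHM1 differs from WT only in the PC->SOM release
# probability (gain-of-function), scaled 2.5x.
FDDI_WT_CIRCUIT = CircuitParams()
FDDI_FHM1_CIRCUIT = CircuitParams(
    pc_to_som_release=ReleaseParams(n_sites=30, p0=0.125, q=0.18),
)


def _draw_connection(spec: dict, genotype: str, rng: np.random.Generator
                     ) -> ReleaseParams:
    n_lo, n_hi = spec["n_sites_range"]
    p_lo, p_hi = spec["p0_range"]
    scale = spec["fhm1_p_scale"] if genotype == "FHM1" else 1.0
    return ReleaseParams(n_sites=int(rng.integers(n_lo, n_hi + 1)),
                         p0=min(1.0, float(rng.uniform(p_lo, p_hi)) * scale),
                         q=spec["q"], quantal_cv=spec["quantal_cv"])


def make_cohort(genotype: str, synapse: str, n_connections: int, seed: int,
                protocol: Protocol | None = None, summary_only: bool = False):
    """Generate a cohort of heterogeneous connections for one preset.

    ``genotype`` is ``"WT"`` or ``"FHM1"``; ``synapse`` one of ``"PC-SOM"``,
    ``"SOM-PC"``, ``"PC-PC"``, ``"FDDI"``. With ``summary_only=True`` the
    PC-SOM/SOM-PC/PC-PC presets return per-connection
    ``(release, mean_amp, failure_fraction)`` tuples from the summary
    sampling path instead of rendered sweep sets.
    """
    if genotype not in ("WT", "FHM1"):
        raise ValueError(f"unknown genotype preset {genotype!r}")
    rng = np.random.default_rng(seed)
    if synapse == "FDDI":
        circuit = FDDI_WT_CIRCUIT if genotype == "WT" else FDDI_FHM1_CIRCUIT
        proto = protocol or Protocol(n_pulses=10, freq=100.0, inter_trial=60.0,
                                     n_sweeps=25, pre_window=100.0,
                                     clamp_mode="voltage")
        return [simulate_fddi_experiment(circuit, proto, rng)
                for _ in range(n_connections)]
    if synapse not in COHORT_PRESETS:
        raise ValueError(f"unknown synapse preset {synapse!r}")
    spec = COHORT_PRESETS[synapse]
    proto = protocol or Protocol(n_pulses=1, freq=25.0, inter_trial=10.0,
                                 n_sweeps=50)
    out = []
    for _ in range(n_connections):
        release = _draw_connection(spec, genotype, rng)
        if summary_only:
            amp, fail, _ = sample_connection_summary(release, spec["stp"],
                                                     proto.n_sweeps, rng)
            out.append((release, amp, fail))
        else:
            noise = NoiseParams(baseline_sd=spec["noise_sd"])
            out.append(simulate_connection_sweeps(release, spec["stp"],
                                                  spec["kernel"], noise,
                                                  proto, rng))
    return out
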