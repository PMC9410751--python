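import numpy as np
import pytest
from hypothesis import settings

from synquant import events, synthdata as sd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def single_site_sweeps():
    """Deterministic single-release-site connection: one 0.5-mV event/sweep."""
    rel = sd.ReleaseParams(n_sites=1, p0=1.0, q=0.5)
    return sd.simulate_connection_sweeps(
        rel, sd.STPParams.none(), sd.KernelParams(), sd.NoiseParams(),
        sd.Protocol(n_pulses=1, n_sweeps=8), seed=0)


@pytest.fixture
def noisy_connection():
    """Low-p 3-site connection with realistic noise, 200 sweeps."""
    rel = sd.ReleaseParams(n_sites=3, p0=0.3, q=0.5, quantal_cv=0.3)
    return sd.simulate_connection_sweeps(
        rel, sd.STPParams.none(), sd.KernelParams(jitter_sd=0.2),
        sd.NoiseParams(baseline_sd=0.03),
        sd.Protocol(n_pulses=1, n_sweeps=200), seed=7)


def make_sweepset(traces, sample_rate=10_000.0, stim_times=(50.0,), **kw):
    traces = np.atleast_2d(np.asarray(traces, float))
    return events.SweepSet(
        traces=traces, sample_rate=sample_rate,
        stim_times=np.asarray(stim_times, float),
        sweep_timestamps=np.arange(traces.shape[0], dtype=float), **kw)
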