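"""Train analysis: decay fits, summation correction, PPF and recovery fits."""

import numpy as np
import pytest

from synquant import events, stp, synthdata as sd
from conftest import make_sweepset

T = np.arange(0, 120, 0.1)


class TestDecayFit:
    def test_single_exponential_recovered(self):
        fit = stp.fit_decay_model(T, 2.0 * np.exp(-T / 20.0))
        assert fit.n_components == 1
        assert fit.taus[0] == pytest.approx(20.0, rel=0.01)
        assert fit.amplitudes[0] == pytest.approx(2.0, rel=0.01)

    def test_two_components_selected_and_recovered(self):
        rng = np.random.default_rng(0)
        y = 0.7 * np.exp(-T / 10.0) + 0.3 * np.exp(-T / 200.0)
        fit = stp.fit_decay_model(T, y + 1e-4 * rng.standard_normal(T.size))
        assert fit.n_components == 2
        assert fit.taus[0] == pytest.approx(10.0, rel=0.05)
        assert fit.taus[1] == pytest.approx(200.0, rel=0.05)

    def test_all_zero_segment_rejected(self):
        with pytest.raises(ValueError):
            stp.fit_decay_model(T, np.zeros_like(T))

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            stp.fit_decay_model(T[:10], np.exp(-T[:10] / 5.0))

    def test_rising_segment_flagged(self):
        fit = stp.fit_decay_model(T, -np.exp(-T / 30.0))
        assert fit.flagged


def _exp_psp_trace(stim_ms, amps, tau=20.0, n_samples=3000, sr=10_000.0):
    """Instant-rise exponential PSPs: the decay is exactly one exponential."""
    t = np.arange(n_samples) / sr * 1000.0
    tr = np.zeros(n_samples)
    for t0, a in zip(stim_ms, amps):
        x = t - t0
        tr += np.where(x >= 0, a * np.exp(-x / tau), 0.0)
    return tr


class TestTemporalSummation:
    def test_two_pulse_closed_form(self):
        """amp1=1, tau=20 ms, second pulse at +40 ms with true amp 1.565:
        the raw second peak reads 1.70 and the correction recovers 1.565."""
        tr = _exp_psp_trace([50.0, 90.0], [1.0, 1.565])
        iso = _exp_psp_trace([50.0, 90.0], [0.0, 1.565])
        base = events.Baseline(0.0, 0.0, (0.0, 50.0))
        sw = make_sweepset([tr], stim_times=(50.0, 90.0))
        prof = stp.correct_temporal_summation(sw, base,
                                              latency_window=(0.0, 10.0))
        # raw peak value at the second stimulus is 1.565 + 1.0*e^-2 = 1.70
        assert tr[900] == pytest.approx(1.70, abs=1e-3)
        iso_amp = events.measure_mean_response(
            make_sweepset([iso], stim_times=(50.0, 90.0)), 1, base,
            latency_window=(0.0, 10.0))
        assert prof.corrected_amps[1] == pytest.approx(iso_amp, abs=1e-8)

    def test_exactness_machine_precision_single_exponential(self):
        """Noiseless single-exponential decays: correction is exact."""
        amps = [0.5, 1.2, 2.0, 2.5]
        stim = [50.0, 90.0, 130.0, 170.0]
        tr = _exp_psp_trace(stim, amps)
        base = events.Baseline(0.0, 0.0, (0.0, 50.0))
        sw = make_sweepset([tr], stim_times=tuple(stim))
        prof = stp.correct_temporal_summation(sw, base,
                                              latency_window=(0.0, 10.0))
        for j, a in enumerate(amps):
            iso = _exp_psp_trace(stim, [x if i == j else 0.0
                                        for i, x in enumerate(amps)])
            ref = events.measure_mean_response(
                make_sweepset([iso], stim_times=tuple(stim)), j, base,
                latency_window=(0.0, 10.0))
            assert prof.corrected_amps[j] == pytest.approx(ref, abs=1e-7)

    def test_no_overlap_correction_is_identity(self):
        """ISI >> tau: corrected equals raw for every pulse."""
        stim = [50.0, 250.0, 450.0]
        tr = _exp_psp_trace(stim, [1.0, 1.5, 2.0], tau=10.0, n_samples=6000)
        sw = make_sweepset([tr], stim_times=tuple(stim))
        prof = stp.correct_temporal_summation(
            sw, events.Baseline(0.0, 0.0, (0.0, 50.0)),
            latency_window=(0.0, 10.0))
        assert np.allclose(prof.corrected_amps, prof.raw_amps, rtol=1e-6)

    @pytest.mark.parametrize("freq,mode", [(25.0, "per-pulse"),
                                           (100.0, "last-pulse")])
    def test_simulated_train_quantal_content(self, freq, mode):
        """Noiseless expected trains: corrected amps match N p_k q within 2%
        (after cancelling the 1-ms window bias via pulse 1)."""
        rel = sd.ReleaseParams(n_sites=3, p0=0.05, q=0.926)
        stpp = sd.STPParams(facil_increment=4.8, tau_facil=54.0)
        kern = sd.KernelParams(latency=1.5, jitter_sd=0.0, rise_tau=1.0,
                               decay_tau=30.0)
        proto = sd.Protocol(n_pulses=5, freq=freq, n_sweeps=1, pre_window=60.0)
        mt = sd.expected_mean_trace(rel, stpp, kern, proto)
        prof = stp.correct_temporal_summation(
            mt, events.Baseline(0.0, 0.0, (0.0, 60.0)), mode=mode)
        expected = sd.expected_pulse_amplitudes(rel, stpp, 1000.0 / freq, 5)
        scale = prof.corrected_amps[0] / expected[0]
        assert np.allclose(prof.corrected_amps, expected * scale, rtol=0.02)


class TestTrainProfile:
    def test_published_ratio_example(self):
        """Amplitudes growing from 0.14 mV to 1.134 mV give r5 = 8.1."""
        prof = stp.train_profile(np.array([0.14, 0.378, 0.63, 0.91, 1.134]))
        assert prof.ratios[4] == pytest.approx(8.1, abs=0.01)
        assert prof.ratios[0] == 1.0

    def test_equal_amplitudes_unit_ratios(self):
        prof = stp.train_profile(np.full(5, 0.3))
        assert np.allclose(prof.ratios, 1.0) and prof.ppr == 1.0

    def test_depression_gives_decreasing_ratios(self):
        """High-p depleting synapse: expected ratios strictly decrease."""
        rel = sd.ReleaseParams(n_sites=5, p0=0.9, q=0.3)
        stpp = sd.STPParams(depletion_enabled=True, tau_recovery=500.0)
        amps = sd.expected_pulse_amplitudes(rel, stpp, 40.0, 5)
        prof = stp.train_profile(amps)
        assert np.all(np.diff(prof.ratios) < 0)

    def test_nonpositive_first_amplitude_rejected(self):
        with pytest.raises(ValueError):
            stp.train_profile(np.array([0.0, 1.0]))


ISI = np.array([10.0, 20.0, 50.0, 100.0, 200.0, 400.0, 800.0, 2000.0])


class TestPPFDecay:
    def test_shared_model_recovers_parameters(self):
        """Identically generated groups: shared fit, tau within 15%."""
        true = 1 + 4.8 * np.exp(-ISI / 54.0)
        n_shared = n_tau = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = 0.05 * true.mean()
            groups = {g: (ISI, true + noise * rng.standard_normal(ISI.size))
                      for g in ("WT", "FHM1")}
            fit = stp.fit_ppf_decay(groups)
            n_shared += fit.shared_selected
            n_tau += abs(fit.shared_tau - 54.0) / 54.0 < 0.15
        assert n_shared >= 16   # ~1 - alpha of 20, allowing binomial spread
        assert n_tau >= 18

    def test_distinct_kinetics_select_separate_model(self):
        groups = {"a": (ISI, 1 + 4.8 * np.exp(-ISI / 20.0)),
                  "b": (ISI, 1 + 4.8 * np.exp(-ISI / 200.0))}
        fit = stp.fit_ppf_decay(groups)
        assert not fit.shared_selected

    def test_underdetermined_input_rejected(self):
        with pytest.raises(ValueError):
            stp.fit_ppf_decay({"a": (np.array([50.0]), np.array([2.0])),
                               "b": (np.array([50.0]), np.array([2.0]))})
        with pytest.raises(ValueError):
            stp.fit_ppf_decay({"a": (ISI, 1 + np.exp(-ISI / 54.0))})


DELAYS = np.array([10.0, 20.0, 35.0, 50.0, 75.0, 100.0, 150.0, 250.0,
                   500.0, 1000.0, 2000.0, 4000.0])
WT_RECOVERY = stp.RecoveryFit(amplitude=2.2, frac_fast=0.79, tau_fast=41.0,
                              tau_slow=1182.0, rss=0.0, constrained=False)


class TestRecoveryFit:
    def test_closed_form_recovery_fraction(self):
        """With the fitted parameter set (A_f=0.79, tau_f=41, tau_s=1182),
        74% of the facilitation has decayed 100 ms after the train."""
        assert WT_RECOVERY.recovery_fraction(100.0) == pytest.approx(0.74,
                                                                     abs=0.005)

    def test_noiseless_parameters_recovered_exactly(self):
        fit = stp.fit_recovery(DELAYS, WT_RECOVERY(DELAYS))
        assert fit.amplitude == pytest.approx(2.2, rel=1e-4)
        assert fit.frac_fast == pytest.approx(0.79, rel=1e-3)
        assert fit.tau_fast == pytest.approx(41.0, rel=1e-3)
        assert fit.tau_slow == pytest.approx(1182.0, rel=1e-2)

    def test_constraint_contract(self):
        fit = stp.fit_recovery(DELAYS, WT_RECOVERY(DELAYS),
                               constrain_tau_fast=54.0)
        assert fit.tau_fast == 54.0 and fit.constrained

    def test_noisy_recovery_within_tolerance(self):
        """5% noise: fast parameters within 25% (tau_slow is known to be
        poorly conditioned and is not asserted tightly)."""
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = WT_RECOVERY(DELAYS) * (
                1 + 0.05 * rng.standard_normal(DELAYS.size))
            fit = stp.fit_recovery(DELAYS, np.clip(y, 0, None))
            ok += (abs(fit.amplitude - 2.2) / 2.2 < 0.25
                   and abs(fit.tau_fast - 41.0) / 41.0 < 0.25)
        assert ok >= 8

    def test_recovery_fraction_monotone_to_one(self):
        t = np.linspace(1.0, 20_000.0, 500)
        rf = WT_RECOVERY.recovery_fraction(t)
        assert np.all(np.diff(rf) > 0)
        assert rf[-1] == pytest.approx(1.0, abs=1e-3)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            stp.fit_recovery(DELAYS[:3], WT_RECOVERY(DELAYS[:3]))

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            stp.fit_recovery(DELAYS, -np.ones(8))


class TestGeneratorLink:
    def test_ppf_tau_matches_generator_tau_facil(self):
        """With facilitation the only STP mechanism, the fitted PPF decay
        time constant equals the generator's tau_facil."""
        rel = sd.ReleaseParams(n_sites=4, p0=0.05, q=0.4)
        stpp = sd.STPParams(facil_increment=4.8, tau_facil=54.0)
        ppr = []
        for isi in ISI:
            amps = sd.expected_pulse_amplitudes(rel, stpp, isi, 2)
            ppr.append(amps[1] / amps[0])
        fit = stp.fit_ppf_decay({"a": (ISI, np.array(ppr)),
                                 "b": (ISI, np.array(ppr))})
        assert fit.shared_tau == pytest.approx(54.0, rel=0.02)
        assert fit.shared_amp == pytest.approx(4.8, rel=0.02)
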