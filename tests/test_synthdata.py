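"""Simulator correctness against closed-form release-model oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synquant import events, fddi, synthdata as sd


class TestReleaseModel:
    def test_deterministic_single_site(self, single_site_sweeps):
        """n_sites=1, p0=1: every sweep one event of peak q, no failures."""
        sweeps, gt = single_site_sweeps
        base = events.baseline_for(sweeps)
        labels = events.classify_trials(sweeps, base, noiseless=True)
        assert labels.failure_fraction[0] == 0.0
        assert np.allclose(labels.amplitudes, 0.5, atol=1e-4)
        assert np.all(gt.release_counts == 1)

    @pytest.mark.parametrize("n_sites,p0", [(1, 0.3), (3, 0.05), (5, 0.2)])
    def test_failure_fraction_matches_binomial(self, n_sites, p0):
        """Observed failure fraction ~ (1-p)^N within 3 binomial SEs."""
        rel = sd.ReleaseParams(n_sites=n_sites, p0=p0, q=0.5)
        rng = np.random.default_rng(42)
        n = 10_000
        _, fail, _ = sd.sample_connection_summary(rel, sd.STPParams.none(),
                                                  n, rng)
        f_true = (1 - p0) ** n_sites
        se = np.sqrt(f_true * (1 - f_true) / n)
        assert abs(fail - f_true) < 3 * se

    def test_trace_path_failure_fraction(self):
        """End-to-end: rendered traces + classification recover (1-p)^N."""
        rel = sd.ReleaseParams(n_sites=3, p0=0.05, q=0.5)
        sweeps, gt = sd.simulate_connection_sweeps(
            rel, sd.STPParams.none(), sd.KernelParams(),
            sd.NoiseParams(baseline_sd=0.005),
            sd.Protocol(n_pulses=1, n_sweeps=4000), seed=3)
        base = events.baseline_for(sweeps)
        labels = events.classify_trials(sweeps, base)
        f_true = 0.95 ** 3
        se = np.sqrt(f_true * (1 - f_true) / 4000)
        assert abs(labels.failure_fraction[0] - f_true) < 3 * se
        # classification agrees with the generator's own release counts
        agree = np.mean(labels.is_event[:, 0] == (gt.release_counts[:, 0] > 0))
        assert agree > 0.99

    def test_mean_amplitude_converges_to_npq(self):
        rel = sd.ReleaseParams(n_sites=4, p0=0.2, q=0.4, quantal_cv=0.25)
        rng = np.random.default_rng(1)
        amp, _, _ = sd.sample_connection_summary(rel, sd.STPParams.none(),
                                                 20_000, rng)
        assert amp == pytest.approx(4 * 0.2 * 0.4, rel=0.03)

    def test_determinism_same_seed(self):
        rel = sd.ReleaseParams(n_sites=3, p0=0.2, q=0.5)
        kw = dict(stp=sd.STPParams(facil_increment=1.0),
                  kernel=sd.KernelParams(jitter_sd=0.3),
                  noise=sd.NoiseParams(baseline_sd=0.05),
                  protocol=sd.Protocol(n_pulses=3, n_sweeps=10))
        a, _ = sd.simulate_connection_sweeps(rel, kw["stp"], kw["kernel"],
                                             kw["noise"], kw["protocol"], 99)
        b, _ = sd.simulate_connection_sweeps(rel, kw["stp"], kw["kernel"],
                                             kw["noise"], kw["protocol"], 99)
        assert np.array_equal(a.traces, b.traces)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sd.ReleaseParams(n_sites=0, p0=0.5, q=1.0)
        with pytest.raises(ValueError):
            sd.ReleaseParams(n_sites=2, p0=1.5, q=1.0)
        with pytest.raises(ValueError):
            sd.ReleaseParams(n_sites=2, p0=0.5, q=-1.0)
        with pytest.raises(ValueError):
            sd.ReleaseParams(n_sites=2, p0=float("nan"), q=1.0)


class TestShortTermPlasticity:
    @given(a_f=st.floats(0.0, 10.0), tau=st.floats(1.0, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_facilitation_factor_never_below_one(self, a_f, tau):
        F = sd.facilitation_factors(sd.STPParams(facil_increment=a_f,
                                                 tau_facil=tau), 10.0, 8)
        assert np.all(F >= 1.0)
        assert F[0] == 1.0

    def test_expected_amps_nondecreasing_without_depletion(self):
        rel = sd.ReleaseParams(n_sites=5, p0=0.05, q=0.3)
        stp = sd.STPParams(facil_increment=2.0, tau_facil=80.0)
        amps = sd.expected_pulse_amplitudes(rel, stp, 40.0, 5)
        assert np.all(np.diff(amps) >= -1e-12)

    def test_facilitation_doubles_second_pulse(self):
        """a_F tuned so p doubles at pulse 2 -> amplitude ratio -> 2."""
        # p2 = p0 * (1 + a_F e^(-isi/tau)); choose a_F so the factor is 2
        isi, tau = 40.0, 54.0
        a_f = 1.0 / np.exp(-isi / tau)
        rel = sd.ReleaseParams(n_sites=3, p0=0.05, q=0.4)
        stp = sd.STPParams(facil_increment=a_f, tau_facil=tau)
        rng = np.random.default_rng(0)
        counts_ratio = []
        _, _, counts = sd.sample_connection_summary(rel, stp, 40_000, rng,
                                                    isi_ms=isi, n_pulses=2)
        ratio = counts[:, 1].mean() / counts[:, 0].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_pure_depression_ppr_below_one(self):
        """p0=1 with depletion: second pulse limited by refill -> PPR < 1."""
        rel = sd.ReleaseParams(n_sites=5, p0=1.0, q=0.3)
        stp = sd.STPParams(depletion_enabled=True, tau_recovery=300.0)
        amps = sd.expected_pulse_amplitudes(rel, stp, 40.0, 2)
        assert amps[1] / amps[0] < 1.0

    def test_rundown_scales_quanta_over_time(self):
        rel = sd.ReleaseParams(n_sites=1, p0=1.0, q=1.0)
        sweeps, gt = sd.simulate_connection_sweeps(
            rel, sd.STPParams.none(), sd.KernelParams(),
            sd.NoiseParams(rundown_rate=0.2),  # 20%/min
            sd.Protocol(n_pulses=1, n_sweeps=5, inter_trial=60.0), seed=0)
        # sweeps at 0..4 min: q scaled 1.0, 0.8, 0.6, 0.4, 0.2
        assert np.allclose(gt.quantal_sums[:, 0], [1.0, 0.8, 0.6, 0.4, 0.2])


class TestSampleRateInvariance:
    def test_peak_amplitude_invariant_to_sample_rate(self):
        rel = sd.ReleaseParams(n_sites=2, p0=1.0, q=0.5)
        amps = {}
        for sr in (10_000.0, 20_000.0, 50_000.0):
            proto = sd.Protocol(n_pulses=1, n_sweeps=1, sample_rate=sr)
            sweeps, _ = sd.simulate_connection_sweeps(
                rel, sd.STPParams.none(), sd.KernelParams(), sd.NoiseParams(),
                proto, seed=0)
            amps[sr] = events.measure_mean_response(
                sweeps, 0, events.Baseline(0.0, 0.0, (0.0, 50.0)))
        ref = amps[50_000.0]
        for sr, a in amps.items():
            assert abs(a - ref) / ref < 0.01


class TestDisynapticCircuit:
    proto = sd.Protocol(n_pulses=10, freq=100.0, inter_trial=60.0,
                        n_sweeps=10, pre_window=100.0, clamp_mode="voltage")

    def test_unreachable_threshold_silences_pc2(self):
        from dataclasses import replace
        circ = replace(sd.FDDI_WT_CIRCUIT, som_threshold=1e6)
        sweeps, gt = sd.simulate_fddi_experiment(circ, self.proto, 1)
        assert all(len(sp) == 0 for sp in gt.som_spike_times)
        assert gt.onset_ms is None
        assert abs(sweeps.mean_trace().mean()) < 1.0  # noise only

    def test_deterministic_onset_matches_integrator_oracle(self):
        """No noise/jitter/variability: ground-truth onset equals the first
        threshold crossing of an independently summed EPSP superposition."""
        from dataclasses import replace
        ek = sd.KernelParams(latency=1.5, jitter_sd=0.0, rise_tau=1.0,
                             decay_tau=30.0)
        circ = replace(sd.FDDI_WT_CIRCUIT, epsp_kernel=ek, ipsc_cv=0.0,
                       noise=sd.NoiseParams(baseline_sd=0.0))
        sweeps, gt = sd.simulate_fddi_experiment(circ, self.proto, 5)
        # oracle: superpose expected EPSPs on a fine grid, find crossing
        stim = self.proto.stim_times_ms()
        amps = sd.expected_pulse_amplitudes(circ.pc_to_som_release,
                                            circ.pc_to_som_stp,
                                            np.diff(stim), 10)
        t = np.arange(0, 300_000) * 0.001  # 1-us grid
        v = np.zeros_like(t)
        for tk, a in zip(stim, amps):
            v += a * sd.psp_kernel(ek, t - tk)
        t_cross = t[np.argmax(v >= circ.som_threshold)]
        expected_onset = t_cross + circ.som_to_pc2_delay - stim[0]
        assert gt.onset_ms == pytest.approx(expected_onset, abs=0.2)

    def test_ipsc_amplitude_scales_charge_linearly(self):
        from dataclasses import replace
        base = replace(sd.FDDI_WT_CIRCUIT, ipsc_cv=0.0,
                       noise=sd.NoiseParams(baseline_sd=0.0))
        doubled = replace(base, ipsc_amp=2 * base.ipsc_amp)
        s1, _ = sd.simulate_fddi_experiment(base, self.proto, 3)
        s2, _ = sd.simulate_fddi_experiment(doubled, self.proto, 3)
        q1 = np.trapezoid(s1.mean_trace())
        q2 = np.trapezoid(s2.mean_trace())
        assert q2 == pytest.approx(2 * q1, rel=1e-6)


class TestCohortPresets:
    def test_wt_pc_som_matches_published_means(self):
        """WT preset: mean amplitude ~0.14 mV, failures ~85%."""
        coh = sd.make_cohort("WT", "PC-SOM", 200, seed=0, summary_only=True)
        amps = np.array([a for _, a, _ in coh])
        fails = np.array([f for _, _, f in coh])
        assert abs(amps.mean() - 0.14) / 0.14 < 0.20
        assert abs(100 * fails.mean() - 85.0) < 5.0

    def test_fhm1_scales_p_not_q(self):
        wt = sd.make_cohort("WT", "PC-SOM", 30, seed=5, summary_only=True)
        fh = sd.make_cohort("FHM1", "PC-SOM", 30, seed=5, summary_only=True)
        assert all(r.q == wt[0][0].q for r, _, _ in fh)
        assert (np.mean([r.p0 for r, _, _ in fh])
                > np.mean([r.p0 for r, _, _ in wt]))

    def test_same_seed_bit_identical(self):
        a = sd.make_cohort("WT", "PC-SOM", 5, seed=11)
        b = sd.make_cohort("WT", "PC-SOM", 5, seed=11)
        for (sa, _), (sb, _) in zip(a, b):
            assert np.array_equal(sa.traces, sb.traces)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            sd.make_cohort("HET", "PC-SOM", 3, seed=0)
        with pytest.raises(ValueError):
            sd.make_cohort("WT", "PC-PV", 3, seed=0)
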