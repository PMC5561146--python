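import numpy as np
import pytest
from scipy import stats as sps

from axoprop import (
    SimulationConfig,
    StimulationSimConfig,
    match_propagating_spikes,
    render_raw_traces,
    simulate_spontaneous,
    simulate_stimulation_session,
)


class TestSpontaneous:
    def test_zero_rates_give_empty_table(self):
        cfg = SimulationConfig(duration_s=10, tonic_rate_hz=0,
                               burst_rate_hz=0, seed=0)
        table, gt = simulate_spontaneous(cfg)
        assert table.n_spikes() == 0
        assert gt.n_emitted() == 0

    def test_zero_jitter_gives_exact_pair_delays(self):
        # 200 µm at 0.5 m/s is exactly 0.4 ms per electrode pair
        cfg = SimulationConfig(duration_s=20, tonic_rate_hz=2,
                               burst_rate_hz=0, n_axons_per_channel=1,
                               true_velocity_m_s=0.5, jitter_ms=0.0,
                               detection_prob=1.0, seed=1)
        table, gt = simulate_spontaneous(cfg)
        for m in range(table.layout.n_modules):
            trains = table.channel_trains(m)
            n = gt.n_emitted(m)
            assert all(t.size == n for t in trains)
            for a, b in zip(trains, trains[1:]):
                np.testing.assert_allclose(b - a, 4e-4, rtol=1e-9)

    def test_tonic_poisson_count_calibration(self):
        # mean spike count over seeds within 3 StDev of rate*duration
        rate, duration = 5.0, 100.0
        counts = []
        for seed in range(20):
            cfg = SimulationConfig(duration_s=duration, tonic_rate_hz=rate,
                                   burst_rate_hz=0, n_axons_per_channel=1,
                                   jitter_ms=0.0, seed=seed)
            _, gt = simulate_spontaneous(cfg)
            counts.extend(a.emission_times.size for a in gt.axons)
        expected = rate * duration
        # 2 ms refractory thins a 5 Hz Poisson train by ~1%
        expected_thinned = expected * (1 - rate * 0.002)
        se = np.sqrt(expected) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected_thinned) < 3 * np.sqrt(expected)
        assert abs(np.mean(counts) - expected_thinned) < 10 * se

    def test_seeded_determinism(self):
        cfg = SimulationConfig(duration_s=15, seed=5)
        t1, _ = simulate_spontaneous(cfg)
        t2, _ = simulate_spontaneous(SimulationConfig(duration_s=15, seed=5))
        for eid in t1.layout.electrode_ids:
            assert np.array_equal(t1.spikes[eid], t2.spikes[eid])

    def test_arrival_rule_matches_ground_truth(self):
        cfg = SimulationConfig(duration_s=10, tonic_rate_hz=3,
                               burst_rate_hz=0, n_axons_per_channel=1,
                               true_velocity_m_s=0.4, jitter_ms=0.0,
                               detection_prob=1.0, seed=2)
        _, gt = simulate_spontaneous(cfg)
        ax = gt.axons[0]
        positions = np.array([100., 300., 500., 700., 900.])
        expected = ax.emission_times[:, None] + positions / 1e6 / 0.4
        np.testing.assert_allclose(ax.arrival_times, expected, atol=1e-12)

    def test_jitter_preserves_arrival_order(self):
        cfg = SimulationConfig(duration_s=30, tonic_rate_hz=5,
                               burst_rate_hz=0, n_axons_per_channel=2,
                               true_velocity_m_s=1.1, jitter_ms=0.1, seed=3)
        _, gt = simulate_spontaneous(cfg)
        for ax in gt.axons:
            if ax.arrival_times.size:
                assert np.all(np.diff(ax.arrival_times, axis=1) > 0)

    def test_detection_prob_thins_arrivals(self):
        cfg = SimulationConfig(duration_s=60, tonic_rate_hz=5,
                               burst_rate_hz=0, detection_prob=0.5,
                               n_axons_per_channel=1, jitter_ms=0.0, seed=4)
        _, gt = simulate_spontaneous(cfg)
        frac = np.mean([a.detected.mean() for a in gt.axons
                        if a.detected.size])
        assert 0.45 < frac < 0.55

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="detection_prob"):
            simulate_spontaneous(SimulationConfig(detection_prob=1.5))


class TestStimulationSession:
    def test_forced_direct_responses(self):
        cfg = SimulationConfig(duration_s=1, tonic_rate_hz=0,
                               burst_rate_hz=0, jitter_ms=0.0, seed=0)
        stim = StimulationSimConfig(n_trials=50, p_direct=1.0, p_late=0.0)
        table, session, gt = simulate_stimulation_session(cfg, stim)
        assert gt.direct_response.all()
        first_el = table.layout.channel_electrodes(0)[1].electrode_id
        ts = table.spikes[first_el]
        assert ts.size == 50
        rel = (ts - session.pulse_times) * 1000.0
        assert np.all((rel >= 5.0) & (rel <= 15.0))
        # nothing after the direct chain has passed (no late responses)
        last_el = table.layout.channel_electrodes(0)[4].electrode_id
        rel_last = (table.spikes[last_el] - session.pulse_times) * 1000.0
        assert np.all(rel_last < 35.0)

    def test_no_responses_no_background_empty(self):
        cfg = SimulationConfig(duration_s=1, tonic_rate_hz=0,
                               burst_rate_hz=0, seed=0)
        stim = StimulationSimConfig(n_trials=20, p_direct=0.0, p_late=0.0)
        table, _, _ = simulate_stimulation_session(cfg, stim)
        assert table.n_spikes() == 0

    def test_pulse_times_at_fixed_intervals(self):
        cfg = SimulationConfig(tonic_rate_hz=0, burst_rate_hz=0, seed=0)
        stim = StimulationSimConfig(n_trials=180, pulse_rate_hz=1.0)
        _, session, _ = simulate_stimulation_session(cfg, stim)
        assert session.n_trials == 180
        np.testing.assert_allclose(np.diff(session.pulse_times), 1.0)

    def test_response_flag_rate_near_p_direct(self):
        flags = []
        for seed in range(20):
            cfg = SimulationConfig(duration_s=1, tonic_rate_hz=0,
                                   burst_rate_hz=0, seed=seed)
            stim = StimulationSimConfig(n_trials=180, p_direct=0.8, p_late=0)
            _, _, gt = simulate_stimulation_session(cfg, stim)
            flags.append(gt.direct_response.mean())
        n = 20 * 180
        ci = sps.norm.ppf(0.995) * np.sqrt(0.8 * 0.2 / n)
        assert abs(np.mean(flags) - 0.8) < ci


class TestRenderRawTraces:
    def test_noise_floor_std(self, layout):
        from axoprop.io_device import SpikeTable

        table = SpikeTable(spikes={eid: np.empty(0)
                                   for eid in layout.electrode_ids},
                           layout=layout, duration_s=1.0)
        cfg = SimulationConfig(noise_sigma_uv=10.0, seed=0)
        rec = render_raw_traces(table, cfg)
        sd = np.std(rec.traces[layout.electrode_ids[0]])
        assert abs(sd - 10.0) < 0.5

    def test_single_spike_trough_amplitude(self, layout):
        from axoprop.io_device import SpikeTable

        spikes = {eid: np.empty(0) for eid in layout.electrode_ids}
        spikes[layout.electrode_ids[0]] = np.array([0.5])
        table = SpikeTable(spikes=spikes, layout=layout, duration_s=1.0)
        cfg = SimulationConfig(amplitude_uv=450.0, noise_sigma_uv=10.0, seed=0)
        rec = render_raw_traces(table, cfg)
        tr = rec.traces[layout.electrode_ids[0]]
        trough_idx = np.argmin(tr)
        assert abs(trough_idx / 25000.0 - 0.5) < 1e-3
        assert -480 < tr[trough_idx] < -420

    def test_snr_in_observed_band(self, layout):
        # amplitude 45 µV over sigma 10 gives SNR ~4.5, inside [2, 35]
        from axoprop.io_device import SpikeTable

        spikes = {eid: np.empty(0) for eid in layout.electrode_ids}
        spikes[layout.electrode_ids[0]] = np.array([0.25, 0.5, 0.75])
        table = SpikeTable(spikes=spikes, layout=layout, duration_s=1.0)
        cfg = SimulationConfig(amplitude_uv=45.0, noise_sigma_uv=10.0, seed=0)
        rec = render_raw_traces(table, cfg)
        tr = rec.traces[layout.electrode_ids[0]]
        snr = -tr.min() / 10.0
        assert 2.0 <= snr <= 35.0

    def test_low_sampling_rate_rejected(self, layout):
        from axoprop.io_device import SpikeTable

        table = SpikeTable(spikes={eid: np.empty(0)
                                   for eid in layout.electrode_ids},
                           layout=layout, duration_s=0.1)
        with pytest.raises(ValueError, match="10 kHz"):
            render_raw_traces(table, SimulationConfig(seed=0),
                              sampling_rate_hz=5000.0)


class TestDownstreamRecovery:
    def test_exact_recovery_without_jitter(self, clean_single_axon_config):
        # matching recovers the emitted count and true velocity exactly
        table, gt = simulate_spontaneous(clean_single_axon_config)
        for m in range(table.layout.n_modules):
            events = match_propagating_spikes(table.channel_trains(m))
            assert len(events) == gt.n_emitted(m)
            for e in events:
                np.testing.assert_allclose(e.pair_velocities, 0.5, rtol=1e-9)
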