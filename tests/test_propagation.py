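import numpy as np
import pytest

from axoprop import (
    MatchParams,
    SimulationConfig,
    channel_velocity_summary,
    match_propagating_spikes,
    propagation_count_correlation,
    proximal_distal_velocities,
    simulate_spontaneous,
    velocity_histogram,
)
from oracles import bin_velocities, maxflow_chain_count, random_channel_instance


def chain_trains(times0, delay_s, n_el=5):
    t0 = np.asarray(times0, dtype=float)
    return [np.sort(t0 + k * delay_s) for k in range(n_el)]


class TestMatchPropagatingSpikes:
    def test_single_chain_at_half_meter_per_second(self):
        events = match_propagating_spikes(chain_trains([0.01], 4e-4))
        assert len(events) == 1
        ev = events[0]
        np.testing.assert_allclose(ev.pair_velocities, 0.5)
        assert ev.mean_velocity == pytest.approx(0.5)
        assert ev.direction == "anterograde"

    def test_incomplete_traversal_yields_no_event(self):
        trains = chain_trains([0.01], 4e-4)
        trains[4] = np.empty(0)      # spike missing on the last electrode
        assert match_propagating_spikes(trains) == []

    def test_wrong_train_count_rejected(self):
        with pytest.raises(ValueError, match="5"):
            match_propagating_spikes(chain_trains([0.01], 4e-4, n_el=4))

    def test_unsorted_train_rejected(self):
        trains = chain_trains([0.01, 0.02], 4e-4)
        trains[2] = trains[2][::-1]
        with pytest.raises(ValueError, match="increasing"):
            match_propagating_spikes(trains)

    def test_delay_window_enforced(self):
        # 2.5 ms pair delay exceeds the 2 ms window: no event
        assert match_propagating_spikes(chain_trains([0.01], 2.5e-3)) == []
        # sub-sample (0.02 ms) delay below min_delay: no event
        assert match_propagating_spikes(chain_trains([0.01], 2e-5)) == []

    def test_velocity_floor_from_window(self):
        # pitch/max_delay: 200 µm / 2 ms = 0.1 m/s
        assert MatchParams().min_velocity_m_s == pytest.approx(0.1)
        events = match_propagating_spikes(chain_trains([0.01, 0.1], 1.9e-3))
        for ev in events:
            assert np.all(ev.pair_velocities >= 0.1)

    def test_event_invariants_on_random_instances(self):
        rng = np.random.default_rng(0)
        params = MatchParams()
        for _ in range(100):
            trains = random_channel_instance(rng)
            for ev in match_propagating_spikes(trains, params):
                assert np.all(np.diff(ev.arrival_times) > 0)
                assert np.all(ev.pair_delays >= params.min_delay_s)
                assert np.all(ev.pair_delays <= params.max_delay_s)
                assert np.all(ev.pair_velocities >= params.min_velocity_m_s)
                assert ev.mean_velocity == pytest.approx(
                    np.mean(ev.pair_velocities))

    def test_injective_consumption(self):
        # two entrance spikes in one window cannot share one partner chain
        trains = chain_trains([0.01], 4e-4)
        trains[0] = np.array([0.0098, 0.01])
        events = match_propagating_spikes(trains)
        assert len(events) == 1

    def test_greedy_equals_maxflow_on_small_instances(self):
        rng = np.random.default_rng(1)
        params = MatchParams()
        for _ in range(200):
            trains = random_channel_instance(rng)
            greedy = len(match_propagating_spikes(trains, params))
            assert greedy == maxflow_chain_count(
                trains, params.min_delay_s, params.max_delay_s)

    def test_two_interleaved_axons_recovered(self):
        rng = np.random.default_rng(2)
        positions = np.array([100.0, 300.0, 500.0, 700.0, 900.0])
        trains = [[] for _ in range(5)]
        n_emit = 0
        for v in (0.4, 0.8):
            em = np.sort(rng.uniform(0, 20.0, 100))
            em = em[np.concatenate([[True], np.diff(em) > 0.005])]
            n_emit += em.size
            for t in em:
                arr = t + positions / 1e6 / v + rng.normal(0, 2e-5, 5)
                arr = np.maximum.accumulate(arr + 1e-9 * np.arange(5))
                for k in range(5):
                    trains[k].append(arr[k])
        trains = [np.sort(np.asarray(t)) for t in trains]
        events = match_propagating_spikes(trains)
        assert len(events) >= 0.98 * n_emit
        v_means = np.array([e.mean_velocity for e in events])
        nearest = np.where(np.abs(v_means - 0.4) < np.abs(v_means - 0.8),
                           0.4, 0.8)
        assert np.all(np.abs(v_means - nearest) / nearest < 0.15)


class TestVelocitySummaries:
    def test_mean_of_event_velocities(self):
        events = match_propagating_spikes(chain_trains([0.01], 5e-4)) + \
            match_propagating_spikes(chain_trains([0.01], 1 / 3e3))
        s = channel_velocity_summary(events)
        assert s.n == 2
        assert s.mean == pytest.approx((0.4 + 0.6) / 2)

    def test_empty_is_missing(self):
        s = channel_velocity_summary([])
        assert s.n == 0 and s.missing and np.isnan(s.mean)

    def test_uniform_velocity_symmetric_split(self):
        events = match_propagating_spikes(chain_trains([0.01], 4e-4))
        prox, dist = proximal_distal_velocities(events)
        assert prox == pytest.approx(0.5)
        assert dist == pytest.approx(0.5)

    def test_segment_split_uses_pair_midpoints(self):
        ev = match_propagating_spikes(chain_trains([0.01], 4e-4))[0]
        ev.pair_velocities = np.array([0.6, 0.6, 0.4, 0.4])
        prox, dist = proximal_distal_velocities([ev])
        assert prox == pytest.approx(0.6)
        assert dist == pytest.approx(0.4)

    def test_segment_velocity_gradient_recovered(self):
        # proximal 0.6 m/s, distal 0.45 m/s axons
        cfg = SimulationConfig(duration_s=60.0, tonic_rate_hz=3.0,
                               burst_rate_hz=0.0, n_axons_per_channel=1,
                               true_velocity_m_s=0.6,
                               true_velocity_distal_m_s=0.45,
                               jitter_ms=0.02, detection_prob=1.0, seed=3)
        table, _ = simulate_spontaneous(cfg)
        events = []
        for m in range(8):
            events += match_propagating_spikes(table.channel_trains(m),
                                               channel_id=m)
        prox, dist = proximal_distal_velocities(events)
        assert abs(prox - 0.6) / 0.6 < 0.05
        assert abs(dist - 0.45) / 0.45 < 0.05


class TestVelocityHistogram:
    def test_eleven_domains(self):
        hist = velocity_histogram([])
        assert hist.n_domains == 11
        np.testing.assert_allclose(hist.bin_edges[0], 0.1)
        np.testing.assert_allclose(hist.bin_edges[-1], 1.2)

    def test_all_in_one_bin(self):
        hist = velocity_histogram(np.full(10, 0.55))
        assert hist.counts[4] == 10
        assert hist.percentages[4] == 100.0

    def test_empty_percentages_undefined(self):
        hist = velocity_histogram([])
        assert hist.counts.sum() == 0
        assert np.all(np.isnan(hist.percentages))

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.normal(0.5, 0.15, 700),
                            rng.normal(0.9, 0.3, 300)])
        hist = velocity_histogram(v)
        counts, overflow = bin_velocities(v)
        np.testing.assert_array_equal(hist.counts, counts)
        assert hist.overflow == overflow
        if hist.counts.sum():
            assert hist.percentages.sum() == pytest.approx(100.0)


class TestCountCorrelation:
    def test_proportional_counts_give_r_one(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        res = propagation_count_correlation(x, 0.5 * x)
        assert res.r == pytest.approx(1.0)

    def test_constant_events_degenerate(self):
        res = propagation_count_correlation(np.array([1.0, 2.0, 3.0]),
                                            np.array([5.0, 5.0, 5.0]))
        assert res.degenerate and res.r == 0.0

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError, match="3"):
            propagation_count_correlation(np.array([1.0, 2.0]),
                                          np.array([1.0, 2.0]))

    def test_known_coupling_recovered(self):
        # bivariate normal with rho=0.5: r within the n=200 sampling CI
        rng = np.random.default_rng(5)
        n = 200
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        res = propagation_count_correlation(x - x.min() + 1.0,
                                            y - y.min() + 1.0)
        z = np.arctanh(res.r) - np.arctanh(0.5)
        assert abs(z) < 2.6 / np.sqrt(n - 3)
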