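"""Synthetic microchannel-MEA data with ground truth.

Emulates the statistical structure the analysis chain assumes: per-axon
spike trains that superpose tonic Poisson firing and compact bursts, spikes
that propagate along the 5 channel electrodes at a per-axon conduction
velocity (0.1-1.2 m/s) with Gaussian timing jitter, probabilistic per-
electrode detection, 1 Hz biphasic stimulation sessions with direct
(5-15 ms) and polysynaptic (late-window) responses, and raw-trace rendering
with biphasic spike templates in Gaussian noise (amplitudes 40-1000 µV,
SNR roughly 2-35).

The generator's purpose is verification: every simulation returns a
:class:`GroundTruth` carrying the hidden parameters (true velocities, burst
intervals, per-trial response flags) that recovery tests compare against.
No biophysics is modelled — arrival times follow the kinematic rule
``arrival_k = emission + position_k / velocity + jitter``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from axoprop.io_device import (
    DeviceLayout,
    Recording,
    SpikeTable,
    build_default_layout,
)
from axoprop.stimulation import StimulationSession

#: absolute refractory period imposed on each axon's emission train (s)
REFRACTORY_S = 0.002


def _validate(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {name}: {msg}")


@dataclass
class SimulationConfig:
    """Parameters of the spontaneous-activity simulation.

    ``true_velocity_m_s`` fixes per-axon velocities (recycled across
    channels); ``None`` draws each axon's velocity from a normal(0.55, 0.15)
    clipped to [0.15, 1.2] m/s, matching the observed velocity-domain range.
    ``true_velocity_distal_m_s`` optionally gives a different velocity for
    the distal half of the channel (beyond 500 µm), to emulate the
    proximal/distal velocity gradient.
    """

    duration_s: float = 60.0
    tonic_rate_hz: float = 0.5
    burst_rate_hz: float = 0.1
    spikes_per_burst_mean: float = 6.0
    intra_burst_isi_ms: float = 7.0
    n_axons_per_channel: int = 3
    true_velocity_m_s: Sequence[float] | float | None = None
    true_velocity_distal_m_s: Sequence[float] | float | None = None
    jitter_ms: float = 0.05
    detection_prob: float = 0.95
    reservoir_fraction: float = 0.5
    amplitude_uv: tuple[float, float] | float = (40.0, 1000.0)
    noise_sigma_uv: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        _validate(self.duration_s > 0, "duration_s", "must be > 0")
        _validate(self.tonic_rate_hz >= 0, "tonic_rate_hz", "must be >= 0")
        _validate(self.burst_rate_hz >= 0, "burst_rate_hz", "must be >= 0")
        _validate(self.spikes_per_burst_mean >= 4,
                  "spikes_per_burst_mean", "bursts need at least 4 spikes")
        _validate(self.intra_burst_isi_ms > 0,
                  "intra_burst_isi_ms", "must be > 0")
        _validate(self.n_axons_per_channel >= 0,
                  "n_axons_per_channel", "must be >= 0")
        _validate(self.jitter_ms >= 0, "jitter_ms", "must be >= 0")
        _validate(0 <= self.detection_prob <= 1,
                  "detection_prob", "must be in [0, 1]")
        _validate(0 <= self.reservoir_fraction <= 1,
                  "reservoir_fraction", "must be in [0, 1]")
        if self.true_velocity_m_s is not None:
            v = np.atleast_1d(np.asarray(self.true_velocity_m_s, dtype=float))
            _validate(bool(np.all(v >= 0.1)),
                      "true_velocity_m_s", "velocities must be >= 0.1 m/s")


@dataclass
class StimulationSimConfig:
    """Parameters of a simulated 1 Hz biphasic stimulation session.

    Direct responses appear within 5-15 ms of the pulse and propagate down
    the channel at ``evoked_velocity_m_s``; polysynaptic responses populate
    the late windows at ``late_velocity_m_s``.
    """

    n_trials: int = 180
    pulse_rate_hz: float = 1.0
    amplitude_mv: float = 500.0
    p_direct: float = 0.8
    p_late: float = 0.3
    direct_latency_ms: tuple[float, float] = (5.0, 15.0)
    late_window_ms: tuple[float, float] = (35.0, 950.0)
    evoked_velocity_m_s: float = 0.6
    late_velocity_m_s: float = 0.5
    artifact_duration_ms: float = 5.0

    def validate(self) -> None:
        _validate(self.n_trials >= 1, "n_trials", "must be >= 1")
        _validate(self.pulse_rate_hz > 0, "pulse_rate_hz", "must be > 0")
        _validate(0 <= self.p_direct <= 1, "p_direct", "must be in [0, 1]")
        _validate(0 <= self.p_late <= 1, "p_late", "must be in [0, 1]")
        lo, hi = self.direct_latency_ms
        _validate(0 < lo < hi, "direct_latency_ms", "need 0 < lo < hi")


@dataclass
class AxonTruth:
    """Hidden parameters of one simulated axon."""

    module_id: int
    axon_index: int
    velocity_m_s: float
    velocity_distal_m_s: float
    emission_times: np.ndarray          # (n_spikes,) s
    arrival_times: np.ndarray           # (n_spikes, 5) s, jitter included
    detected: np.ndarray                # (n_spikes, 5) bool
    burst_intervals: list[tuple[float, float, int]] = field(default_factory=list)
    feeds_reservoir: str | None = None  # electrode_id or None


@dataclass
class GroundTruth:
    """Everything the simulator knows and the analysis must recover."""

    axons: list[AxonTruth]
    config: SimulationConfig
    # stimulation mode only:
    pulse_times: np.ndarray | None = None
    direct_response: np.ndarray | None = None   # (n_trials,) bool
    late_response: np.ndarray | None = None     # (n_trials,) bool

    def axons_of_module(self, module_id: int) -> list[AxonTruth]:
        return [a for a in self.axons if a.module_id == module_id]

    def n_emitted(self, module_id: int | None = None) -> int:
        axons = self.axons if module_id is None else self.axons_of_module(module_id)
        return int(sum(a.emission_times.size for a in axons))


# ---------------------------------------------------------------------------
# emission-train building blocks

def _tonic_train(rng: np.random.Generator, rate_hz: float,
                 duration_s: float) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _burst_trains(rng: np.random.Generator, cfg: SimulationConfig
                  ) -> tuple[np.ndarray, list[tuple[float, float, int]]]:
    """Burst spikes plus per-burst (start, end, n_spikes) intervals.

    Intra-burst ISIs are drawn uniformly within ±20% of the configured mean
    (7 ms default), which keeps them under the 10 ms burst-extension bound
    and yields >= 21 ms duration at the 4-spike minimum, so generated bursts
    satisfy the MaxInterval criteria by construction.
    """
    if cfg.burst_rate_hz <= 0:
        return np.empty(0), []
    n_bursts = rng.poisson(cfg.burst_rate_hz * cfg.duration_s)
    onsets = np.sort(rng.uniform(0.0, cfg.duration_s, size=n_bursts))
    isi_s = cfg.intra_burst_isi_ms / 1000.0
    spikes: list[np.ndarray] = []
    intervals: list[tuple[float, float, int]] = []
    prev_end = -np.inf
    for onset in onsets:
        if onset < prev_end + 0.05:   # keep bursts well separated (50 ms)
            continue
        n_sp = 4 + rng.poisson(max(cfg.spikes_per_burst_mean - 4.0, 0.0))
        isis = rng.uniform(0.8 * isi_s, 1.2 * isi_s, size=n_sp - 1)
        ts = onset + np.concatenate([[0.0], np.cumsum(isis)])
        ts = ts[ts < cfg.duration_s]
        if ts.size >= 4:
            spikes.append(ts)
            intervals.append((float(ts[0]), float(ts[-1]), int(ts.size)))
            prev_end = float(ts[-1])
    if not spikes:
        return np.empty(0), []
    return np.concatenate(spikes), intervals


def _apply_refractory(ts: np.ndarray, dead_s: float = REFRACTORY_S) -> np.ndarray:
    """Drop spikes closer than ``dead_s`` to the previous kept spike."""
    if ts.size <= 1:
        return ts
    keep = [0]
    last = ts[0]
    for i in range(1, ts.size):
        if ts[i] - last >= dead_s:
            keep.append(i)
            last = ts[i]
    return ts[keep]


def _arrival_times(emission: np.ndarray, positions_um: np.ndarray,
                   v_prox: float, v_dist: float, jitter_s: float,
                   rng: np.random.Generator, split_um: float = 500.0
                   ) -> np.ndarray:
    """Kinematic arrival times (n_spikes, n_electrodes), jitter included.

    Jitter is additive Gaussian per electrode, redrawn (up to 20 times, then
    clipped) so the arrival order along the channel is preserved — the
    matching stage assumes monotone arrivals.
    """
    prox = np.minimum(positions_um, split_um)
    dist = np.maximum(positions_um - split_um, 0.0)
    travel = prox / 1e6 / v_prox + dist / 1e6 / v_dist      # seconds
    base = emission[:, None] + travel[None, :]
    if jitter_s == 0:
        return base
    arr = base + rng.normal(0.0, jitter_s, size=base.shape)
    for _ in range(20):
        bad = np.any(np.diff(arr, axis=1) <= 0, axis=1)
        if not np.any(bad):
            break
        arr[bad] = base[bad] + rng.normal(0.0, jitter_s,
                                          size=(int(bad.sum()), base.shape[1]))
    # any remaining non-monotone rows: clip to preserve order
    for i in np.flatnonzero(np.any(np.diff(arr, axis=1) <= 0, axis=1)):
        for k in range(1, arr.shape[1]):
            arr[i, k] = max(arr[i, k], arr[i, k - 1] + 1e-6)
    return arr


def _axon_velocities(cfg: SimulationConfig, n_axons: int,
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    if cfg.true_velocity_m_s is None:
        v = np.clip(rng.normal(0.55, 0.15, size=n_axons), 0.15, 1.2)
    else:
        v = np.resize(np.atleast_1d(
            np.asarray(cfg.true_velocity_m_s, dtype=float)), n_axons)
    if cfg.true_velocity_distal_m_s is None:
        v_dist = v.copy()
    else:
        v_dist = np.resize(np.atleast_1d(
            np.asarray(cfg.true_velocity_distal_m_s, dtype=float)), n_axons)
    return v, v_dist


def _simulate_axons(cfg: SimulationConfig, layout: DeviceLayout,
                    rng: np.random.Generator) -> list[AxonTruth]:
    axons: list[AxonTruth] = []
    jitter_s = cfg.jitter_ms / 1000.0
    for m in range(layout.n_modules):
        positions = np.array(
            [e.position_um for e in layout.channel_electrodes(m)], dtype=float)
        res_ids = [e.electrode_id for e in layout.reservoir_electrodes(m)]
        v_prox, v_dist = _axon_velocities(cfg, cfg.n_axons_per_channel, rng)
        for a in range(cfg.n_axons_per_channel):
            tonic = _tonic_train(rng, cfg.tonic_rate_hz, cfg.duration_s)
            burst_sp, burst_iv = _burst_trains(rng, cfg)
            emission = _apply_refractory(
                np.sort(np.concatenate([tonic, burst_sp])))
            # keep every arrival inside the recording: drop emissions whose
            # travel time (+ jitter headroom) would pass the end
            margin = positions[-1] / 1e6 / min(v_prox[a], v_dist[a]) \
                + 6.0 * jitter_s
            emission = emission[emission < cfg.duration_s - margin]
            burst_iv = [iv for iv in burst_iv
                        if iv[1] < cfg.duration_s - margin]
            arrivals = _arrival_times(emission, positions,
                                      v_prox[a], v_dist[a], jitter_s, rng)
            if cfg.detection_prob >= 1.0:
                detected = np.ones(arrivals.shape, dtype=bool)
            else:
                detected = rng.random(arrivals.shape) < cfg.detection_prob
            feeds = None
            if res_ids and rng.random() < cfg.reservoir_fraction:
                feeds = res_ids[rng.integers(len(res_ids))]
            axons.append(AxonTruth(
                module_id=m, axon_index=a,
                velocity_m_s=float(v_prox[a]),
                velocity_distal_m_s=float(v_dist[a]),
                emission_times=emission, arrival_times=arrivals,
                detected=detected, burst_intervals=burst_iv,
                feeds_reservoir=feeds,
            ))
    return axons


def _table_from_axons(axons: list[AxonTruth], layout: DeviceLayout,
                      duration_s: float, metadata: dict,
                      extra: dict[str, list[np.ndarray]] | None = None
                      ) -> SpikeTable:
    """Assemble per-electrode trains from axon arrivals (+ optional extras)."""
    per_electrode: dict[str, list[np.ndarray]] = {
        eid: [] for eid in layout.electrode_ids}
    for ax in axons:
        chan = layout.channel_electrodes(ax.module_id)
        for k, el in enumerate(chan):
            ts = ax.arrival_times[ax.detected[:, k], k]
            if ts.size:
                per_electrode[el.electrode_id].append(ts)
        if ax.feeds_reservoir is not None and ax.emission_times.size:
            per_electrode[ax.feeds_reservoir].append(ax.emission_times)
    if extra:
        for eid, chunks in extra.items():
            per_electrode.setdefault(eid, []).extend(chunks)
    spikes = {}
    for eid, chunks in per_electrode.items():
        if chunks:
            ts = np.sort(np.concatenate(chunks))
            ts = ts[(ts >= 0) & (ts <= duration_s)]
            # collapse coincidences below 1 µs: indistinguishable at 25 kHz
            if ts.size > 1:
                ts = ts[np.concatenate([[True], np.diff(ts) > 1e-6])]
            spikes[eid] = ts
        else:
            spikes[eid] = np.empty(0)
    return SpikeTable(spikes=spikes, layout=layout,
                      duration_s=duration_s, metadata=metadata)


def simulate_spontaneous(config: SimulationConfig,
                         layout: DeviceLayout | None = None
                         ) -> tuple[SpikeTable, GroundTruth]:
    """Simulate spontaneous tonic + burst activity on the whole device.

    Each axon's emission train is a superposition of a homogeneous Poisson
    process (``tonic_rate_hz``) and Poisson-onset bursts, thinned by a 2 ms
    refractory period.  Every emitted spike is projected to the five channel
    electrodes through the arrival rule and independently kept with
    ``detection_prob``; a configurable fraction of axons also contributes
    its emission-time train to one reservoir electrode of its module.
    Deterministic for a given config (seed included).
    """
    config.validate()
    if layout is None:
        layout = build_default_layout()
    rng = np.random.default_rng(config.seed)
    axons = _simulate_axons(config, layout, rng)
    metadata = {"kind": "simulated_spontaneous", "seed": config.seed}
    table = _table_from_axons(axons, layout, config.duration_s, metadata)
    return table, GroundTruth(axons=axons, config=config)


def simulate_stimulation_session(config: SimulationConfig,
                                 stim: StimulationSimConfig,
                                 layout: DeviceLayout | None = None,
                                 module_id: int = 0
                                 ) -> tuple[SpikeTable, StimulationSession, GroundTruth]:
    """Simulate one axonal-stimulation session on ``module_id``.

    Pulses are applied at the first (entrance-proximal) channel electrode at
    fixed ``1/pulse_rate_hz`` intervals.  Each trial inserts, with
    probability ``p_direct``, a direct chain at a uniform 5-15 ms latency
    that propagates over the four recording electrodes at the evoked
    velocity; with probability ``p_late`` one polysynaptic chain at a
    uniform latency inside the late window.  Spontaneous background from
    ``config`` is superimposed (set its rates to 0 for a clean session).
    """
    config.validate()
    stim.validate()
    if layout is None:
        layout = build_default_layout()
    rng = np.random.default_rng(config.seed)

    period = 1.0 / stim.pulse_rate_hz
    pulse_times = np.arange(stim.n_trials) * period
    duration = pulse_times[-1] + period
    if config.duration_s < duration:
        config = SimulationConfig(**{**config.__dict__, "duration_s": duration})

    chan = layout.channel_electrodes(module_id)
    rec_els = chan[1:]                      # 4 electrodes distal to stim site
    positions = np.array([e.position_um for e in rec_els], dtype=float)
    rel_pos = positions - positions[0]
    jitter_s = config.jitter_ms / 1000.0

    direct_flag = rng.random(stim.n_trials) < stim.p_direct
    late_flag = rng.random(stim.n_trials) < stim.p_late
    lat_lo, lat_hi = stim.direct_latency_ms
    extra: dict[str, list[np.ndarray]] = {e.electrode_id: [] for e in rec_els}

    def insert_chain(t0: float, velocity: float) -> None:
        arr = _arrival_times(np.array([t0]), rel_pos, velocity, velocity,
                             jitter_s, rng)[0]
        for k, el in enumerate(rec_els):
            extra[el.electrode_id].append(np.array([arr[k]]))

    for i, pt in enumerate(pulse_times):
        if direct_flag[i]:
            latency = rng.uniform(lat_lo, lat_hi) / 1000.0
            insert_chain(pt + latency, stim.evoked_velocity_m_s)
        if late_flag[i]:
            late = rng.uniform(*stim.late_window_ms) / 1000.0
            insert_chain(pt + late, stim.late_velocity_m_s)

    axons = _simulate_axons(config, layout, rng)
    metadata = {"kind": "simulated_stimulation", "seed": config.seed,
                "module_id": module_id, "amplitude_mv": stim.amplitude_mv}
    table = _table_from_axons(axons, layout, duration, metadata, extra=extra)
    session = StimulationSession(
        pulse_times=pulse_times,
        amplitude_mv=stim.amplitude_mv,
        n_trials=stim.n_trials,
        stim_electrode_id=chan[0].electrode_id,
        blanking_ms=stim.artifact_duration_ms,
    )
    truth = GroundTruth(axons=axons, config=config, pulse_times=pulse_times,
                        direct_response=direct_flag, late_response=late_flag)
    return table, session, truth


def default_response_probs(amplitude_mv: float) -> tuple[float, float]:
    """Amplitude-dependent (p_direct, p_late) defaults.

    Higher pulse amplitudes elicit direct responses more reliably and
    recruit polysynaptic activity; 250 mV pulses rarely drive late
    responses.
    """
    if amplitude_mv >= 1000:
        return 0.95, 0.5
    if amplitude_mv >= 500:
        return 0.9, 0.4
    return 0.7, 0.05


# ---------------------------------------------------------------------------
# raw-trace rendering

def _spike_template(sampling_rate_hz: float) -> np.ndarray:
    """Negative-leading biphasic template, ~1 ms support, trough = -1."""
    n = max(int(round(sampling_rate_hz * 1e-3)), 10)
    t = np.linspace(0.0, 1.0, n)
    wave = -np.exp(-((t - 0.3) / 0.12) ** 2) + 0.45 * np.exp(
        -((t - 0.62) / 0.18) ** 2)
    return wave / -wave.min()


def render_raw_traces(table: SpikeTable, config: SimulationConfig,
                      session: StimulationSession | None = None,
                      sampling_rate_hz: float = 25000.0) -> Recording:
    """Render a SpikeTable into raw voltage traces.

    Each timestamp becomes a biphasic template (negative-leading, ~1 ms)
    scaled to the configured amplitude, summed into white Gaussian noise of
    ``noise_sigma_uv``.  Stimulation pulses, if a session is given, become
    saturating artifacts of ``blanking_ms`` duration on every electrode.
    """
    if sampling_rate_hz < 10000:
        raise ValueError("sampling rate < 10 kHz cannot resolve the template")
    rng = np.random.default_rng(config.seed + 1)
    n_samples = int(np.ceil(table.duration_s * sampling_rate_hz)) + 1
    template = _spike_template(sampling_rate_hz)
    trough_off = int(np.argmin(template))
    amp = config.amplitude_uv
    traces: dict[str, np.ndarray] = {}
    for eid in table.layout.electrode_ids:
        tr = rng.normal(0.0, config.noise_sigma_uv, size=n_samples)
        ts = table.get(eid)
        if np.isscalar(amp):
            amps = np.full(ts.size, float(amp))
        else:
            lo, hi = amp
            amps = np.exp(rng.uniform(np.log(lo), np.log(hi), size=ts.size))
        for t, a in zip(ts, amps):
            i0 = int(round(t * sampling_rate_hz)) - trough_off
            j0, j1 = max(i0, 0), min(i0 + template.size, n_samples)
            if j1 > j0:
                tr[j0:j1] += a * template[j0 - i0:j1 - i0]
        if session is not None:
            n_art = int(round(session.blanking_ms / 1000.0 * sampling_rate_hz))
            for pt in session.pulse_times:
                i0 = int(round(pt * sampling_rate_hz))
                j1 = min(i0 + n_art, n_samples)
                if i0 < n_samples:
                    tr[i0:j1] = 2000.0 * np.sign(
                        np.sin(np.arange(j1 - i0) * 0.5) + 0.5)
        traces[eid] = tr
    return Recording(traces=traces, sampling_rate_hz=sampling_rate_hz,
                     layout=table.layout, metadata=dict(table.metadata))


# ---------------------------------------------------------------------------
# scenario generators for the correlation analyses

def simulate_age_coupled_features(n_modules: int = 42,
                                  divs: Sequence[int] = (13, 18, 23, 31, 38,
                                                         45, 52, 63, 74, 95),
                                  seed: int = 0):
    """Module-by-DIV burst features and velocities both driven by age.

    Emulates the maturation confound: culture age raises burst rate and
    conduction velocity in parallel, while within one recording day the two
    vary independently.  Pooling all days therefore produces a positive
    feature-velocity correlation that vanishes when each day is analysed
    separately.

    Returns two tidy DataFrames (features, velocities) keyed by
    (module_id, div).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    divs = np.asarray(divs, dtype=float)
    age = (divs - divs.min()) / (divs.max() - divs.min())   # 0..1
    rows_f, rows_v = [], []
    for m in range(n_modules):
        for d, a in zip(divs, age):
            burst_rate = 0.05 + 0.25 * a + rng.normal(0.0, 0.02)
            spike_rate = 0.5 + 3.0 * a + rng.normal(0.0, 0.3)
            velocity = 0.46 + 0.12 * a + rng.normal(0.0, 0.04)
            rows_f.append({"module_id": m, "div": int(d),
                           "burst_rate": max(burst_rate, 0.0),
                           "spike_rate": max(spike_rate, 0.0)})
            rows_v.append({"module_id": m, "div": int(d),
                           "velocity": max(velocity, 0.1)})
    return pd.DataFrame(rows_f), pd.DataFrame(rows_v)


def simulate_disinhibition(n_channels: int = 32, rate_factor: float = 3.0,
                           seed: int = 0):
    """Per-channel paired baseline/disinhibited feature tables.

    Emulates GABA-A blockade: spike and burst rates rise ~``rate_factor``-
    fold while the conduction velocity is unchanged up to measurement noise.
    Returns (baseline, treated) DataFrames indexed by channel.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    base_rate = rng.lognormal(np.log(2.0), 0.5, size=n_channels)
    base_burst = rng.lognormal(np.log(0.15), 0.4, size=n_channels)
    base_vel = np.clip(rng.normal(0.6, 0.1, size=n_channels), 0.2, 1.2)
    baseline = pd.DataFrame({
        "spike_rate": base_rate,
        "burst_rate": base_burst,
        "velocity": base_vel + rng.normal(0.0, 0.02, size=n_channels),
    }, index=pd.RangeIndex(n_channels, name="channel"))
    treated = pd.DataFrame({
        "spike_rate": base_rate * rate_factor
        * rng.lognormal(0.0, 0.1, size=n_channels),
        "burst_rate": base_burst * rate_factor
        * rng.lognormal(0.0, 0.1, size=n_channels),
        "velocity": base_vel + rng.normal(0.0, 0.02, size=n_channels),
    }, index=pd.RangeIndex(n_channels, name="channel"))
    return baseline, treated
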