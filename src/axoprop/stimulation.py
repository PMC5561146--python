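"""Peri-stimulus analysis of electrically evoked responses.

Sessions deliver biphasic voltage pulses (positive-then-negative, 100 µs
per phase) at 1 Hz.  The first 5 ms after each pulse is blanked as
stimulation artifact; direct responses fall in the 5-35 ms window,
polysynaptic activity in 35-950 ms.  Response fidelity is the percentage
of the 180 trials with at least one spike in a 10 ms bin, and evoked
conduction velocity is measured by chain-matching over the four electrodes
distal to the stimulation site, split by the window of each chain's first
arrival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from axoprop.io_device import DeviceLayout, SpikeTable


@dataclass
class StimulationSession:
    """One stimulation run: pulse times, amplitude, protocol constants."""

    pulse_times: np.ndarray
    amplitude_mv: float
    n_trials: int = 0
    stim_electrode_id: str | None = None
    phase_us: float = 100.0
    polarity: str = "positive-then-negative"
    blanking_ms: float = 5.0

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.n_trials == 0:
            self.n_trials = self.pulse_times.size
        if self.n_trials != self.pulse_times.size:
            raise ValueError("n_trials must equal len(pulse_times)")

    @property
    def min_spacing_s(self) -> float:
        if self.pulse_times.size < 2:
            return math.inf
        return float(np.min(np.diff(self.pulse_times)))


@dataclass
class WindowScheme:
    """Post-stimulus windows in ms.

    ``windows`` are the analysis windows for rates, ``direct``/``late``
    split evoked from polysynaptic activity, and ``fidelity_bins`` are the
    three 10 ms bins partitioning 5-35 ms used for response fidelity.
    """

    windows: list[tuple[float, float]] = field(default_factory=lambda: [
        (5.0, 15.0), (15.0, 35.0), (35.0, 100.0),
        (100.0, 300.0), (300.0, 950.0)])
    direct: tuple[float, float] = (5.0, 35.0)
    late: tuple[float, float] = (35.0, 950.0)
    fidelity_bins: list[tuple[float, float]] = field(default_factory=lambda: [
        (5.0, 15.0), (15.0, 25.0), (25.0, 35.0)])
    trial_end_ms: float = 1000.0

    def validate(self, blanking_ms: float = 5.0) -> None:
        for ws in (self.windows, self.fidelity_bins):
            for (a, b) in ws:
                if b <= a:
                    raise ValueError(f"zero/negative-length window ({a}, {b})")
                if a < blanking_ms or b > self.trial_end_ms:
                    raise ValueError(
                        f"window ({a}, {b}) outside (blanking, trial end)")
            for (a0, b0), (a1, b1) in zip(ws, ws[1:]):
                if a1 < b0:
                    raise ValueError("windows overlap")


@dataclass
class PeristimulusRaster:
    """Per-trial, per-electrode spike times relative to the pulse (ms).

    ``trials[eid][i]`` holds electrode ``eid``'s relative timestamps for
    trial ``i``, already blanked; ``blank_counts`` counts discarded
    within-blanking spikes per electrode.
    """

    trials: dict[str, list[np.ndarray]]
    n_trials: int
    blank_counts: dict[str, int]
    blanking_ms: float

    def pooled_trial_times(self, electrodes: list[str] | None = None
                           ) -> list[np.ndarray]:
        """Per-trial relative times pooled over the selected electrodes."""
        eids = list(self.trials) if electrodes is None else electrodes
        out = []
        for i in range(self.n_trials):
            chunks = [self.trials[e][i] for e in eids if e in self.trials]
            out.append(np.sort(np.concatenate(chunks)) if chunks
                       else np.empty(0))
        return out


def align_peristimulus(table: SpikeTable, session: StimulationSession,
                       scheme: WindowScheme | None = None
                       ) -> PeristimulusRaster:
    """Align spikes to their stimulation pulse.

    Each trial covers ``(blanking_ms, trial_end_ms]`` after its pulse;
    spikes inside the blanking period are discarded but counted.  Raises if
    pulses are spaced closer than the trial window, which would assign one
    spike to two trials.
    """
    scheme = scheme or WindowScheme()
    scheme.validate(session.blanking_ms)
    if session.min_spacing_s * 1000.0 < scheme.trial_end_ms:
        raise ValueError(
            "pulse spacing shorter than the trial window; shorten the "
            "window scheme or the session is ill-formed")
    blank_s = session.blanking_ms / 1000.0
    end_s = scheme.trial_end_ms / 1000.0
    trials: dict[str, list[np.ndarray]] = {}
    blank_counts: dict[str, int] = {}
    for eid, ts in table.spikes.items():
        per_trial = []
        blanked = 0
        for pt in session.pulse_times:
            lo = np.searchsorted(ts, pt, side="left")
            hi = np.searchsorted(ts, pt + end_s, side="right")
            rel = (ts[lo:hi] - pt) * 1000.0     # ms
            blanked += int(np.sum(rel <= session.blanking_ms))
            per_trial.append(rel[rel > session.blanking_ms])
        trials[eid] = per_trial
        blank_counts[eid] = blanked
    return PeristimulusRaster(trials=trials, n_trials=session.n_trials,
                              blank_counts=blank_counts,
                              blanking_ms=session.blanking_ms)


def window_rates(raster: PeristimulusRaster,
                 scheme: WindowScheme | None = None,
                 electrodes: list[str] | None = None
                 ) -> dict[tuple[float, float], tuple[float, float]]:
    """Mean rate (spikes/s) +/- StDev across trials for each window.

    Rates pool the selected electrodes: rate = total spikes in the window
    across trials / (n_trials x window length); the StDev is over per-trial
    rates.
    """
    scheme = scheme or WindowScheme()
    trial_times = raster.pooled_trial_times(electrodes)
    out = {}
    for (a, b) in scheme.windows:
        if b <= a:
            raise ValueError("zero-length window")
        length_s = (b - a) / 1000.0
        counts = np.array([np.sum((t >= a) & (t < b)) for t in trial_times],
                          dtype=float)
        rates = counts / length_s
        std = float(np.std(rates, ddof=1)) if len(rates) > 1 else math.nan
        out[(a, b)] = (float(np.mean(rates)), std)
    return out


def response_fidelity(raster: PeristimulusRaster,
                      scheme: WindowScheme | None = None,
                      electrodes: list[str] | None = None
                      ) -> dict[tuple[float, float], float]:
    """Percentage of trials with >= 1 spike in each fidelity bin.

    A trial is positive for a bin when any selected electrode fired at
    least once inside it; spike multiplicity within the bin is irrelevant.
    """
    scheme = scheme or WindowScheme()
    if raster.n_trials == 0:
        raise ValueError("no trials")
    trial_times = raster.pooled_trial_times(electrodes)
    out = {}
    for (a, b) in scheme.fidelity_bins:
        positive = sum(bool(np.any((t >= a) & (t < b))) for t in trial_times)
        out[(a, b)] = 100.0 * positive / raster.n_trials
    return out


def evoked_velocity(table: SpikeTable, session: StimulationSession,
                    match_params=None, scheme: WindowScheme | None = None,
                    module_id: int = 0):
    """Per-window conduction velocity of evoked propagating spikes.

    Chain-matching runs over the four electrodes distal to the stimulation
    site (3 pairs); each complete chain is assigned to the direct or late
    window by the peri-stimulus time of its first arrival.  Returns
    {"direct": VelocitySummary, "late": VelocitySummary}; a window without
    events carries a missing summary (n = 0).  Apply the same function to a
    non-stimulated recording with a surrogate session for baselines.
    """
    from axoprop.propagation import (MatchParams, VelocitySummary,
                                     _chain_events)

    match_params = match_params or MatchParams()
    scheme = scheme or WindowScheme()
    chan = table.layout.channel_electrodes(module_id)
    trains = [table.get(e.electrode_id) for e in chan[1:]]
    events = _chain_events(trains, match_params, channel_id=module_id)

    pulses = session.pulse_times
    window_v: dict[str, list[float]] = {"direct": [], "late": []}
    for ev in events:
        t0 = ev.arrival_times[0]
        k = np.searchsorted(pulses, t0, side="right") - 1
        if k < 0:
            continue
        rel_ms = (t0 - pulses[k]) * 1000.0
        for name, (a, b) in (("direct", scheme.direct), ("late", scheme.late)):
            if a <= rel_ms < b:
                window_v[name].extend(ev.pair_velocities)
    out = {}
    for name, vs in window_v.items():
        if vs:
            v = np.asarray(vs)
            std = float(np.std(v, ddof=1)) if v.size > 1 else math.nan
            out[name] = VelocitySummary(mean=float(np.mean(v)), std=std,
                                        n=v.size)
        else:
            out[name] = VelocitySummary(mean=math.nan, std=math.nan, n=0)
    return out
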