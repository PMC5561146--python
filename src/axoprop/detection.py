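"""Spike detection: Bessel high-pass filtering and robust negative threshold.

The detection chain mirrors a standard MEA acquisition pipeline: a
second-order Bessel high-pass at 200 Hz removes field potentials and drift,
a robust noise scale sigma is estimated from the filtered trace, and spikes
are timestamps of negative threshold crossings at -4.5 sigma, one event per
dead-time window, placed at the trough sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from axoprop.io_device import Recording, SpikeTable

#: MAD -> sigma for Gaussian noise
_MAD_TO_SIGMA = 1.4826


@dataclass
class DetectionParams:
    filter_order: int = 2
    filter_cutoff_hz: float = 200.0
    threshold_factor: float = 4.5
    dead_time_ms: float = 1.0
    noise_window_s: float = 0.1
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.filter_cutoff_hz <= 0:
            raise ValueError("filter_cutoff_hz must be > 0")
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be > 0")
        if self.dead_time_ms < 0:
            raise ValueError("dead_time_ms must be >= 0")


def highpass_filter(trace: np.ndarray, sampling_rate_hz: float,
                    params: DetectionParams | None = None) -> np.ndarray:
    """Second-order Bessel high-pass (cut-off = -3 dB point).

    Applied forward-only (causal) by default, matching an online acquisition
    chain; ``params.zero_phase`` switches to filtfilt, which removes group
    delay but is non-causal — leave it off when timestamps feed latency
    computations.
    """
    params = params or DetectionParams()
    if params.filter_cutoff_hz >= sampling_rate_hz / 2:
        raise ValueError("filter cutoff must be below Nyquist")
    sos = signal.bessel(params.filter_order, params.filter_cutoff_hz,
                        btype="highpass", norm="mag",
                        fs=sampling_rate_hz, output="sos")
    trace = np.asarray(trace, dtype=float)
    if params.zero_phase:
        return signal.sosfiltfilt(sos, trace)
    return signal.sosfilt(sos, trace)


def estimate_noise(trace: np.ndarray,
                   params: DetectionParams | None = None,
                   sampling_rate_hz: float = 25000.0) -> float:
    """Robust, spike-insensitive noise scale of a filtered trace (µV).

    The trace is cut into ``noise_window_s`` windows; sigma is the median
    across windows of the per-window MAD-based standard deviation.  The
    median over windows discards windows inflated by bursts, and the MAD
    within a window discards isolated spikes, so sparse large spikes barely
    bias the estimate.  Returns 0.0 for an all-zero trace.
    """
    params = params or DetectionParams()
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0 or not np.any(trace):
        return 0.0
    win = max(int(round(params.noise_window_s * sampling_rate_hz)), 16)
    n_win = max(trace.size // win, 1)
    sigmas = []
    for i in range(n_win):
        seg = trace[i * win:(i + 1) * win]
        mad = np.median(np.abs(seg - np.median(seg)))
        sigmas.append(_MAD_TO_SIGMA * mad)
    return float(np.median(sigmas))


def detect_spikes(trace: np.ndarray, sampling_rate_hz: float,
                  params: DetectionParams | None = None,
                  sigma: float | None = None) -> np.ndarray:
    """Timestamps (s) of negative threshold crossings on a filtered trace.

    Threshold is ``-threshold_factor * sigma``; each crossing run yields one
    event at its trough sample, and events closer than ``dead_time_ms`` to
    the previous accepted event are suppressed.  Output is strictly
    increasing.
    """
    params = params or DetectionParams()
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    if sigma is None:
        sigma = estimate_noise(trace, params, sampling_rate_hz)
    if sigma == 0:
        return np.empty(0)
    threshold = -params.threshold_factor * sigma
    below = trace < threshold
    if not np.any(below):
        return np.empty(0)
    # contiguous runs of sub-threshold samples
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.concatenate([[0], starts])
    if below[-1]:
        ends = np.concatenate([ends, [trace.size]])
    dead = params.dead_time_ms / 1000.0
    times: list[float] = []
    last = -np.inf
    for s, e in zip(starts, ends):
        trough = s + int(np.argmin(trace[s:e]))
        t = trough / sampling_rate_hz
        if t - last >= dead:
            times.append(t)
            last = t
    return np.asarray(times)


def detect_recording(rec: Recording,
                     params: DetectionParams | None = None) -> SpikeTable:
    """Filter + threshold every electrode of a Recording; per-electrode sigma."""
    params = params or DetectionParams()
    spikes = {}
    for eid, raw in rec.traces.items():
        filt = highpass_filter(raw, rec.sampling_rate_hz, params)
        spikes[eid] = detect_spikes(filt, rec.sampling_rate_hz, params)
    return SpikeTable(spikes=spikes, layout=rec.layout,
                      duration_s=rec.duration_s,
                      metadata=dict(rec.metadata))
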