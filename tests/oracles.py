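"""Independent reference implementations used as test oracles.

These deliberately take different computational routes from the package:
max-flow for the chain-matching optimum, a pure-Python interval scan for
bursts, the analog transfer function for the digital filter, and plain
loops for binning.  They are slow and simple on purpose.
"""

from __future__ import annotations

import numpy as np


def maxflow_chain_count(trains, min_delay_s: float, max_delay_s: float) -> int:
    """Maximum number of disjoint complete chains, via vertex-capacity max flow.

    Each spike is a unit-capacity node; edges connect spikes on consecutive
    electrodes whose delay lies in the window.  The max s-t flow equals the
    largest possible number of vertex-disjoint entrance-to-exit chains,
    independent of any greedy order.
    """
    import networkx as nx

    G = nx.DiGraph()
    n_el = len(trains)
    for k, tr in enumerate(trains):
        for i, t in enumerate(tr):
            G.add_edge(("in", k, i), ("out", k, i), capacity=1)
            if k == 0:
                G.add_edge("s", ("in", 0, i), capacity=1)
            if k == n_el - 1:
                G.add_edge(("out", k, i), "t", capacity=1)
    for k in range(n_el - 1):
        for i, t in enumerate(trains[k]):
            for j, u in enumerate(trains[k + 1]):
                if min_delay_s <= u - t <= max_delay_s:
                    G.add_edge(("out", k, i), ("in", k + 1, j), capacity=1)
    if "s" not in G or "t" not in G:
        return 0
    return int(nx.maximum_flow_value(G, "s", "t"))


def reference_bursts(train_s, max_isi_start_ms=20.0, max_isi_end_ms=10.0,
                     min_ibi_ms=10.0, min_duration_ms=20.0, min_spikes=4):
    """Plain-Python burst scan: returns list of (first_idx, last_idx).

    Works in milliseconds on Python lists; merge-then-filter order.
    """
    ts = [t * 1000.0 for t in train_s]
    n = len(ts)
    cands = []
    i = 0
    while i < n - 1:
        if ts[i + 1] - ts[i] <= max_isi_start_ms:
            j = i + 1
            while j < n - 1 and ts[j + 1] - ts[j] <= max_isi_end_ms:
                j += 1
            cands.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for c in cands:
        if merged and ts[c[0]] - ts[merged[-1][1]] < min_ibi_ms:
            merged[-1][1] = c[1]
        else:
            merged.append(c)
    out = []
    for a, b in merged:
        if (b - a + 1) >= min_spikes and (ts[b] - ts[a]) >= min_duration_ms:
            out.append((a, b))
    return out


def bessel2_highpass_gain(freq_hz: float, cutoff_hz: float) -> float:
    """|H(j2πf)| of the analog 2nd-order Bessel high-pass, -3 dB at cutoff.

    The magnitude-normalised 2nd-order Bessel low-pass prototype is
    H(s) = k / (s² + 1.361654 s + 0.618034); the high-pass follows from
    s -> ωc²·(prototype)/..., i.e. denominator s² + 1.361654 ωc s +
    0.618034 ωc² with numerator s².
    """
    wc = 2 * np.pi * cutoff_hz
    s = 1j * 2 * np.pi * freq_hz
    return float(abs(s ** 2 / (s ** 2 + 1.3616541 * wc * s
                               + 0.6180340 * wc ** 2)))


def bin_velocities(velocities, lo=0.1, hi=1.2, width=0.1):
    """Plain-loop binning into [lo, hi] domains; returns (counts, overflow)."""
    n_bins = int(round((hi - lo) / width))
    counts = [0] * n_bins
    overflow = 0
    for v in velocities:
        if v < lo or v > hi:
            overflow += 1
            continue
        k = int((v - lo) / width)
        if k == n_bins:          # v == hi belongs to the last bin
            k = n_bins - 1
        counts[k] += 1
    return np.array(counts), overflow


def random_channel_instance(rng, n_el=5, max_spikes=12, duration_s=0.5,
                            pitch_um=200.0):
    """One random microchannel instance: axon chains + background spikes.

    Emulates recorded channel activity: 1-3 axons at fixed velocities
    emitting Poisson-like spikes that arrive with small jitter, plus
    uncorrelated background events, capped at ``max_spikes`` per electrode.
    """
    positions = pitch_um / 2.0 + pitch_um * np.arange(n_el)
    trains = [[] for _ in range(n_el)]
    for _ in range(rng.integers(1, 4)):
        v = rng.uniform(0.15, 1.1)
        for t in np.sort(rng.uniform(0, duration_s, rng.integers(0, 4))):
            arr = t + positions / 1e6 / v + rng.normal(0, 2e-5, n_el)
            arr = np.maximum.accumulate(arr + np.arange(n_el) * 1e-9)
            for k in range(n_el):
                trains[k].append(arr[k])
    out = []
    for k in range(n_el):
        extra = rng.uniform(0, duration_s, rng.integers(0, 4))
        ts = np.sort(np.unique(np.concatenate([np.asarray(trains[k]), extra])))
        out.append(ts[:max_spikes])
    return out
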