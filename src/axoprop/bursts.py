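"""MaxInterval-style burst detection and burst features.

A burst is a compact group of spikes satisfying five criteria: a maximum
inter-spike interval (ISI) to start the burst (20 ms), a maximum ISI to
extend it (10 ms), a minimum inter-burst interval below which neighbouring
candidates are merged (10 ms), a minimum duration (20 ms) and a minimum
spike count (4).  Candidate bursts are merged before the duration/count
filters are applied — the minimum inter-burst interval is meaningless
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class BurstCriteria:
    max_isi_start_ms: float = 20.0
    max_isi_end_ms: float = 10.0
    min_ibi_ms: float = 10.0
    min_duration_ms: float = 20.0
    min_spikes: int = 4

    def __post_init__(self) -> None:
        for name in ("max_isi_start_ms", "max_isi_end_ms",
                     "min_ibi_ms", "min_duration_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_isi_end_ms > self.max_isi_start_ms:
            raise ValueError("max_isi_end_ms must not exceed max_isi_start_ms")
        if self.min_spikes < 1:
            raise ValueError("min_spikes must be >= 1")


@dataclass(frozen=True)
class Burst:
    """One detected burst: spike indices [first, last] into the train."""

    start_s: float
    end_s: float
    first_index: int
    last_index: int

    @property
    def n_spikes(self) -> int:
        return self.last_index - self.first_index + 1

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BurstFeatures:
    """The eight per-train features used in the activity-velocity analysis.

    Means over bursts are NaN (missing) when the train has no bursts;
    mean_ibi_s additionally needs at least two bursts.
    """

    spike_rate: float
    burst_rate: float
    pct_spikes_in_bursts: float
    mean_burst_duration_s: float
    mean_spikes_per_burst: float
    mean_sf_in_burst: float
    mean_isi_in_burst_s: float
    mean_ibi_s: float

    FIELDS = ("spike_rate", "burst_rate", "pct_spikes_in_bursts",
              "mean_burst_duration_s", "mean_spikes_per_burst",
              "mean_sf_in_burst", "mean_isi_in_burst_s", "mean_ibi_s")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS}


def detect_bursts(train: np.ndarray,
                  criteria: BurstCriteria | None = None) -> list[Burst]:
    """Detect bursts in a sorted spike train (timestamps in seconds).

    Scan semantics: a candidate opens at the first spike of an ISI <=
    max_isi_start and extends while subsequent ISIs are <= max_isi_end.
    Candidates separated by less than min_ibi are merged, then candidates
    shorter than min_duration or with fewer than min_spikes are discarded.
    A burst cannot open on the final spike — an ISI is required to open one.
    """
    criteria = criteria or BurstCriteria()
    train = np.asarray(train, dtype=float)
    if train.size and np.any(np.diff(train) <= 0):
        raise ValueError("spike train must be strictly increasing")
    if train.size < 2:
        return []
    isi = np.diff(train)
    start_s = criteria.max_isi_start_ms / 1000.0
    end_s = criteria.max_isi_end_ms / 1000.0
    # candidate detection
    candidates: list[tuple[int, int]] = []
    i = 0
    n_isi = isi.size
    while i < n_isi:
        if isi[i] <= start_s:
            j = i + 1
            while j < n_isi and isi[j] <= end_s:
                j += 1
            candidates.append((i, j))        # spikes i..j inclusive
            i = j + 1
        else:
            i += 1
    # merge candidates separated by < min_ibi
    ibi_s = criteria.min_ibi_ms / 1000.0
    merged: list[tuple[int, int]] = []
    for c in candidates:
        if merged and train[c[0]] - train[merged[-1][1]] < ibi_s:
            merged[-1] = (merged[-1][0], c[1])
        else:
            merged.append(c)
    # duration / spike-count filters
    dur_s = criteria.min_duration_ms / 1000.0
    out = []
    for a, b in merged:
        if b - a + 1 >= criteria.min_spikes and train[b] - train[a] >= dur_s:
            out.append(Burst(start_s=float(train[a]), end_s=float(train[b]),
                             first_index=a, last_index=b))
    return out


def burst_features(train: np.ndarray, bursts: list[Burst],
                   duration_s: float) -> BurstFeatures:
    """Compute the eight burst features for one electrode's train."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    train = np.asarray(train, dtype=float)
    n_total = train.size
    nan = math.nan
    spike_rate = n_total / duration_s
    if not bursts:
        return BurstFeatures(spike_rate=spike_rate, burst_rate=0.0,
                             pct_spikes_in_bursts=0.0 if n_total else nan,
                             mean_burst_duration_s=nan,
                             mean_spikes_per_burst=nan,
                             mean_sf_in_burst=nan,
                             mean_isi_in_burst_s=nan,
                             mean_ibi_s=nan)
    n_in = sum(b.n_spikes for b in bursts)
    durations = np.array([b.duration_s for b in bursts])
    counts = np.array([b.n_spikes for b in bursts], dtype=float)
    # per-burst spike frequency and mean intra-burst ISI
    sf = counts / durations
    isi_means = np.array([
        np.mean(np.diff(train[b.first_index:b.last_index + 1]))
        for b in bursts
    ])
    if len(bursts) >= 2:
        ibis = np.array([bursts[k + 1].start_s - bursts[k].end_s
                         for k in range(len(bursts) - 1)])
        mean_ibi = float(np.mean(ibis))
    else:
        mean_ibi = nan
    return BurstFeatures(
        spike_rate=spike_rate,
        burst_rate=len(bursts) / duration_s,
        pct_spikes_in_bursts=100.0 * n_in / n_total,
        mean_burst_duration_s=float(np.mean(durations)),
        mean_spikes_per_burst=float(np.mean(counts)),
        mean_sf_in_burst=float(np.mean(sf)),
        mean_isi_in_burst_s=float(np.mean(isi_means)),
        mean_ibi_s=mean_ibi,
    )
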