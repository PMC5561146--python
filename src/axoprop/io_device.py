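"""Device geometry and on-disk formats.

The recording platform couples a PDMS microchannel device to a 60-electrode
MEA: eight reservoir modules (somal compartments) each drain their axons into
one 1 mm microchannel lined with five electrodes at 200 µm pitch; two further
electrodes record from each reservoir module.  This module defines the layout
description, the in-memory containers for raw traces and spike timestamps,
and their serialisation (HDF5 for traces, CSV + JSON sidecar for spikes).

Units: time in seconds, distance in µm, voltage in µV, velocity in m/s
(``v[m/s] = Δx[µm] / (Δt[s] × 1e6)``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

#: maximum number of cells seeded into one reservoir module
MAX_CELLS_PER_MODULE = 200

ROLE_RESERVOIR = "reservoir"
ROLE_CHANNEL = "channel"


class SchemaError(ValueError):
    """A file's layout or metadata does not match the expected schema."""


@dataclass(frozen=True)
class Electrode:
    """One MEA electrode and its place in the device geometry.

    ``channel_index`` runs 0..4 along the microchannel; index 0 is the
    electrode nearest the reservoir (the stimulation-proximal site).
    ``position_um`` is the distance from the channel entrance; it is ``None``
    for reservoir electrodes, whose in-module position carries no analysis
    meaning.
    """

    electrode_id: str
    module_id: int
    role: str
    channel_index: int | None = None
    position_um: float | None = None


@dataclass
class DeviceLayout:
    """Electrode-to-module/microchannel geometry."""

    n_modules: int
    electrodes: list[Electrode]
    pitch_um: float = 200.0
    channel_length_um: float = 1000.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        if self.channel_length_um < 4 * self.pitch_um:
            raise ValueError(
                "channel_length_um must cover at least 4 electrode pitches"
            )
        ids = [e.electrode_id for e in self.electrodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate electrode_id in layout")
        for m in range(self.n_modules):
            res = [e for e in self.electrodes
                   if e.module_id == m and e.role == ROLE_RESERVOIR]
            cha = self.channel_electrodes(m)
            if len(res) != 2:
                raise ValueError(f"module {m}: expected 2 reservoir electrodes")
            if len(cha) != 5:
                raise ValueError(f"module {m}: expected 5 channel electrodes")
            pos = np.array([e.position_um for e in cha], dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"module {m}: channel positions not increasing")
            if not np.allclose(np.diff(pos), self.pitch_um):
                raise ValueError(f"module {m}: channel spacing != pitch_um")
            if pos[0] < 0 or pos[-1] > self.channel_length_um:
                raise ValueError(f"module {m}: positions outside channel")

    def channel_electrodes(self, module_id: int) -> list[Electrode]:
        """Channel electrodes of one module, ordered entrance -> exit."""
        els = [e for e in self.electrodes
               if e.module_id == module_id and e.role == ROLE_CHANNEL]
        return sorted(els, key=lambda e: e.channel_index)

    def reservoir_electrodes(self, module_id: int) -> list[Electrode]:
        return [e for e in self.electrodes
                if e.module_id == module_id and e.role == ROLE_RESERVOIR]

    @property
    def electrode_ids(self) -> list[str]:
        return [e.electrode_id for e in self.electrodes]

    def to_dict(self) -> dict:
        return {
            "n_modules": self.n_modules,
            "pitch_um": self.pitch_um,
            "channel_length_um": self.channel_length_um,
            "electrodes": [
                {
                    "electrode_id": e.electrode_id,
                    "module_id": e.module_id,
                    "role": e.role,
                    "channel_index": e.channel_index,
                    "position_um": e.position_um,
                }
                for e in self.electrodes
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DeviceLayout":
        try:
            electrodes = [Electrode(**rec) for rec in d["electrodes"]]
            return cls(
                n_modules=d["n_modules"],
                electrodes=electrodes,
                pitch_um=d["pitch_um"],
                channel_length_um=d["channel_length_um"],
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed layout record: {exc}") from exc


def build_default_layout() -> DeviceLayout:
    """The standard 8-module device.

    Eight reservoir modules, each with 2 reservoir electrodes and 5
    microchannel electrodes at 200 µm pitch along a 1 mm channel; channel
    electrode positions are 100, 300, 500, 700 and 900 µm from the entrance
    (56 electrode records in total).
    """
    electrodes: list[Electrode] = []
    for m in range(8):
        for r in range(2):
            electrodes.append(
                Electrode(f"m{m}_res{r}", m, ROLE_RESERVOIR)
            )
        for k in range(5):
            electrodes.append(
                Electrode(f"m{m}_ch{k}", m, ROLE_CHANNEL,
                          channel_index=k, position_um=100.0 + 200.0 * k)
            )
    return DeviceLayout(n_modules=8, electrodes=electrodes,
                        pitch_um=200.0, channel_length_um=1000.0)


def device_cell_capacity(layout: DeviceLayout,
                         cells_per_module: int = MAX_CELLS_PER_MODULE) -> int:
    """Maximum cell count for a device: modules x per-module seeding maximum."""
    return layout.n_modules * cells_per_module


@dataclass
class Recording:
    """Raw multi-channel extracellular voltage traces.

    ``traces`` maps electrode_id to a 1-D float array in µV; all traces share
    one sampling rate and length.
    """

    traces: dict[str, np.ndarray]
    sampling_rate_hz: float
    layout: DeviceLayout
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError("all traces must have equal length")
        for eid, tr in self.traces.items():
            if not np.all(np.isfinite(tr)):
                raise ValueError(f"non-finite samples on electrode {eid}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.traces.values()))) if self.traces else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class SpikeTable:
    """Per-electrode sorted spike timestamps (seconds)."""

    spikes: dict[str, np.ndarray]
    layout: DeviceLayout
    duration_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for eid in list(self.spikes):
            ts = np.asarray(self.spikes[eid], dtype=float)
            self.spikes[eid] = ts
            if ts.size and (np.any(np.diff(ts) <= 0)):
                raise ValueError(f"timestamps not strictly increasing on {eid}")
            if ts.size and (ts[0] < 0 or ts[-1] > self.duration_s):
                raise ValueError(f"timestamps outside recording on {eid}")

    def get(self, electrode_id: str) -> np.ndarray:
        return self.spikes.get(electrode_id, np.empty(0))

    def channel_trains(self, module_id: int) -> list[np.ndarray]:
        """The 5 channel-electrode trains of one module, entrance -> exit."""
        return [self.get(e.electrode_id)
                for e in self.layout.channel_electrodes(module_id)]

    def n_spikes(self, electrode_id: str | None = None) -> int:
        if electrode_id is not None:
            return int(self.get(electrode_id).size)
        return int(sum(v.size for v in self.spikes.values()))


# ---------------------------------------------------------------------------
# serialisation

def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording to HDF5 (one dataset per electrode)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
        f.attrs["layout_json"] = json.dumps(rec.layout.to_dict())
        f.attrs["metadata_json"] = json.dumps(rec.metadata)
        g = f.create_group("traces")
        for eid, tr in rec.traces.items():
            g.create_dataset(eid, data=np.asarray(tr, dtype=np.float64))
    return path


def load_recording(path: str | Path) -> Recording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for attr in ("sampling_rate_hz", "layout_json", "metadata_json"):
            if attr not in f.attrs:
                raise SchemaError(f"recording file missing attribute {attr!r}")
        if "traces" not in f:
            raise SchemaError("recording file missing group 'traces'")
        layout = DeviceLayout.from_dict(json.loads(f.attrs["layout_json"]))
        traces = {eid: f["traces"][eid][()] for eid in f["traces"]}
        return Recording(
            traces=traces,
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            layout=layout,
            metadata=json.loads(f.attrs["metadata_json"]),
        )


def save_spike_table(table: SpikeTable, path: str | Path) -> Path:
    """Write a SpikeTable as CSV (electrode_id,timestamp_s) + JSON sidecar.

    Timestamps are printed with 17 significant digits, which round-trips
    IEEE-754 doubles bit-exactly.
    """
    path = Path(path)
    rows = [(eid, t) for eid, ts in table.spikes.items() for t in ts]
    df = pd.DataFrame(rows, columns=["electrode_id", "timestamp_s"])
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "layout": table.layout.to_dict(),
        "duration_s": table.duration_s,
        "metadata": table.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    return path


def load_spike_table(path: str | Path) -> SpikeTable:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        layout = DeviceLayout.from_dict(sidecar["layout"])
        duration = float(sidecar["duration_s"])
        metadata = sidecar["metadata"]
    except (KeyError, json.JSONDecodeError) as exc:
        raise SchemaError(f"malformed sidecar: {exc}") from exc
    # round_trip parser: the default fast path loses the last ulp
    df = pd.read_csv(path, dtype={"electrode_id": str, "timestamp_s": float},
                     float_precision="round_trip")
    if list(df.columns) != ["electrode_id", "timestamp_s"]:
        raise SchemaError(
            f"spike CSV columns {list(df.columns)} != "
            "['electrode_id', 'timestamp_s']"
        )
    spikes = {
        eid: np.sort(grp["timestamp_s"].to_numpy())
        for eid, grp in df.groupby("electrode_id", sort=False)
    }
    # electrodes without spikes are implicit: restore empty trains
    for eid in layout.electrode_ids:
        spikes.setdefault(eid, np.empty(0))
    return SpikeTable(spikes=spikes, layout=layout,
                      duration_s=duration, metadata=metadata)
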