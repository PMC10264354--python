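"""Multi-rate recording container and its HDF5 serialization.

A :class:`Recording` holds named channels sampled at possibly different
rates (EEG at 250 Hz; EGG/ECG/SCR/stethoscope at 1000 Hz in the reference
protocol) plus the block annotation (baseline / normal / enhanced spans).
Multichannel signals (the 31-channel EEG) live in a single 2-D
:class:`Channel` with per-row labels.

On disk a session is one HDF5 file with layout
``/channels/<name>/{data,rate,units[,labels]}`` and the block table in a
root attribute.  Datasets are written with ``track_times=False`` so repeated
writes of identical content are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["Channel", "Block", "Recording", "write_recording", "read_recording_hdf5"]


@dataclass
class Channel:
    """A uniformly sampled signal (1-D) or signal bundle (2-D, rows=channels)."""

    name: str
    data: np.ndarray
    rate: float
    units: str = ""
    labels: list[str] | None = None  # row labels for 2-D data
    clock_offset: float = 0.0  # s; cross-device sync correction (TTL alignment)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim == 2 and self.labels is not None and len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match number of rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate + self.clock_offset

    def crop(self, start: float, stop: float) -> "Channel":
        """Return the samples in [start, stop) seconds (relative to session clock)."""
        i0 = max(0, int(np.round((start - self.clock_offset) * self.rate)))
        i1 = min(self.n_samples, int(np.round((stop - self.clock_offset) * self.rate)))
        return Channel(self.name, self.data[..., i0:i1], self.rate, self.units,
                       self.labels, self.clock_offset + i0 / self.rate)


@dataclass(frozen=True)
class Block:
    label: str  # baseline | normal | enhanced
    start: float
    stop: float

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("block stop must exceed start")

    @property
    def duration(self) -> float:
        return self.stop - self.start

    @property
    def span(self) -> tuple[float, float]:
        return (self.start, self.stop)


@dataclass
class Recording:
    channels: dict[str, Channel] = field(default_factory=dict)
    blocks: list[Block] = field(default_factory=list)

    def __getitem__(self, name: str) -> Channel:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def add(self, ch: Channel) -> None:
        self.channels[ch.name] = ch

    def block(self, label: str) -> Block:
        for b in self.blocks:
            if b.label == label:
                return b
        raise KeyError(f"no block labelled {label!r}")


def write_recording(rec: Recording, path) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        g = f.create_group("channels", track_order=True)
        for name in sorted(rec.channels):
            ch = rec.channels[name]
            cg = g.create_group(name)
            cg.create_dataset("data", data=ch.data, track_times=False)
            cg.create_dataset("rate", data=float(ch.rate), track_times=False)
            cg.create_dataset("units", data=np.bytes_(ch.units), track_times=False)
            if ch.labels is not None:
                cg.create_dataset("labels", data=np.array(ch.labels, dtype="S16"),
                                  track_times=False)
            cg.attrs["clock_offset"] = ch.clock_offset
        f.attrs["blocks"] = json.dumps(
            [{"label": b.label, "start": b.start, "stop": b.stop} for b in rec.blocks]
        )


def read_recording_hdf5(path) -> Recording:
    rec = Recording()
    with h5py.File(path, "r") as f:
        for name, cg in f["channels"].items():
            labels = None
            if "labels" in cg:
                labels = [s.decode() for s in cg["labels"][()]]
            rec.add(Channel(
                name=name,
                data=cg["data"][()],
                rate=float(cg["rate"][()]),
                units=cg["units"][()].decode(),
                labels=labels,
                clock_offset=float(cg.attrs.get("clock_offset", 0.0)),
            ))
        for b in json.loads(f.attrs.get("blocks", "[]")):
            rec.blocks.append(Block(b["label"], b["start"], b["stop"]))
    return rec
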