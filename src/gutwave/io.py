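"""Session serialization, format adapters, and pipeline configuration.

A synthetic or recorded session is one directory:

* ``recording.h5``       — channel container (``/channels/<name>/{data,rate,units}``)
* ``events.csv``         — stimulus intervals (onset_s, offset_s, block, condition, kind)
* ``presses.csv``        — button press/release times
* ``ground_truth.json``  — generator ground truth (synthetic sessions only)

Real recordings can also be read from BrainVision triplets or EDF; a
minimal BrainVision writer is provided for round-trip testing.  The
pipeline configuration is YAML with strict key validation, and its SHA-256
hash plus seed are embedded in every pipeline output for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .channels import Channel, Recording, read_recording_hdf5, write_recording
from .montage import EEG_CHANNELS, MASTOIDS
from .synth import EffectParams, ResponderParams, SessionConfig

__all__ = ["write_session", "read_session", "read_recording", "events_to_frame",
           "PipelineConfig", "write_brainvision"]


def events_to_frame(events) -> pd.DataFrame:
    rows = []
    for ev in events:
        if isinstance(ev, dict):
            rows.append({"onset_s": ev["onset_s"], "offset_s": ev["offset_s"],
                         "block": ev.get("block"), "condition": ev.get("condition"),
                         "kind": ev.get("kind", "vibration")})
        else:
            rows.append({"onset_s": ev.onset, "offset_s": ev.offset,
                         "block": getattr(ev, "condition", None),
                         "condition": getattr(ev, "condition", None),
                         "kind": "vibration"})
    return pd.DataFrame(rows, columns=["onset_s", "offset_s", "block", "condition", "kind"])


def write_session(out_dir, rec: Recording, events, presses, ground_truth=None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_recording(rec, out / "recording.h5")
    events_to_frame(events).to_csv(out / "events.csv", index=False)
    press_t, release_t = presses
    pd.DataFrame({"press_s": press_t, "release_s": release_t}).to_csv(
        out / "presses.csv", index=False)
    if ground_truth is not None:
        ground_truth.to_json(out / "ground_truth.json")
    return out


def read_session(session_dir):
    d = Path(session_dir)
    rec = read_recording_hdf5(d / "recording.h5")
    events = pd.read_csv(d / "events.csv").to_dict("records")
    presses = pd.read_csv(d / "presses.csv")
    gt = None
    gt_path = d / "ground_truth.json"
    if gt_path.exists():
        gt = json.loads(gt_path.read_text())
    return rec, events, (presses["press_s"].to_numpy(), presses["release_s"].to_numpy()), gt


# --------------------------------------------------------------------------
# external formats

def read_recording(path, format: str = "hdf5", require_mastoids: bool = True,
                   require_ecg: bool = True) -> Recording:
    """Read a recording from HDF5, a BrainVision triplet, or EDF.

    EEG channels recognized by their 10-20 labels are bundled into one
    multichannel ``eeg`` entry in µV; other channels keep their (lowercased)
    names and native units.
    """
    if format == "hdf5":
        return read_recording_hdf5(path)
    import mne
    if format == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif format == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown recording format {format!r}")
    rec = Recording()
    names = raw.ch_names
    eeg_names = [c for c in names if c in EEG_CHANNELS]
    if eeg_names:
        data = raw.get_data(picks=eeg_names) * 1e6  # V -> µV
        rec.add(Channel("eeg", data, raw.info["sfreq"], "uV", labels=eeg_names))
        if require_mastoids and not all(m in eeg_names for m in MASTOIDS):
            raise ValueError("recording lacks the mastoid channels TP9/TP10")
    for c in names:
        if c in eeg_names:
            continue
        unit = "uS" if "scr" in c.lower() or "gsr" in c.lower() else "mV"
        scale = 1e6 if unit == "uS" else 1e3
        rec.add(Channel(c.lower(), raw.get_data(picks=[c])[0] * scale,
                        raw.info["sfreq"], unit))
    if require_ecg and not any("ecg" in c.lower() for c in rec.channels):
        raise ValueError("recording lacks an ECG channel")
    return rec


def write_brainvision(basename, data_uv: np.ndarray, rate: float,
                      labels: list[str]) -> Path:
    """Minimal BrainVision writer (IEEE float32, multiplexed), for testing
    the read path; returns the .vhdr path."""
    base = Path(basename)
    vhdr, vmrk, eeg = base.with_suffix(".vhdr"), base.with_suffix(".vmrk"), base.with_suffix(".eeg")
    data = np.asarray(data_uv, dtype=np.float32)
    if data.ndim != 2 or data.shape[0] != len(labels):
        raise ValueError("data must be channels x samples matching labels")
    data.T.tofile(eeg)  # multiplexed: sample-major
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "", "[Common Infos]", "Codepage=UTF-8",
        f"DataFile={eeg.name}", f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY", "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(labels)}",
        f"SamplingInterval={1e6 / rate:g}",
        "", "[Binary Infos]", "BinaryFormat=IEEE_FLOAT_32",
        "", "[Channel Infos]",
    ]
    for i, lab in enumerate(labels, 1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg.name}\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,0\n", encoding="utf-8")
    return vhdr


# --------------------------------------------------------------------------
# pipeline configuration

_STAGES = ("simulate", "detect", "score", "erp", "cluster", "egg", "periphys", "stats")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; unknown YAML keys are rejected."""

    out_dir: str = "gutwave_report"
    seed: int = 0
    n_subjects: int = 5
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    session: dict = field(default_factory=dict)   # SessionConfig field overrides
    grace_s: float = 1.0
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    cf_alpha: float = 0.05
    adjacency_max_dist: float = 0.4
    n_pseudo: int = 60
    pseudo_skip_s: float = 120.0
    figures: bool = False
    save_recordings: bool = False
    sessions_dir: str | None = None               # load instead of simulate

    def __post_init__(self):
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggles: {sorted(unknown)}")
        full = {s: True for s in _STAGES}
        full.update(self.stages)
        self.stages = full
        allowed = {f.name for f in dataclasses.fields(SessionConfig)}
        bad = set(self.session) - allowed
        if bad:
            raise ValueError(f"unknown session keys: {sorted(bad)}")
        for sub, cls in (("responder", ResponderParams), ("effects", EffectParams)):
            if sub in self.session and isinstance(self.session[sub], dict):
                subbad = set(self.session[sub]) - {f.name for f in dataclasses.fields(cls)}
                if subbad:
                    raise ValueError(f"unknown {sub} keys: {sorted(subbad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - allowed
        if bad:
            raise ValueError(f"unknown configuration keys: {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        # out_dir is where the report lands, not part of the analysis; leaving
        # it out keeps the provenance hash (and bundle bytes) location-free
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def session_config(self, seed: int) -> SessionConfig:
        kw = dict(self.session)
        if isinstance(kw.get("responder"), dict):
            kw["responder"] = ResponderParams(**kw["responder"])
        if isinstance(kw.get("effects"), dict):
            kw["effects"] = EffectParams(**kw["effects"])
        if isinstance(kw.get("rates"), dict):
            base = {"eeg": 250.0, "ecg": 1000.0, "egg": 1000.0, "scr": 1000.0,
                    "stetho": 1000.0}
            base.update(kw["rates"])
            kw["rates"] = base
        if "channels" in kw:
            kw["channels"] = tuple(kw["channels"])
        if "block_plan" in kw:
            kw["block_plan"] = [tuple(b) for b in kw["block_plan"]]
        kw["seed"] = seed
        return SessionConfig(**kw)
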