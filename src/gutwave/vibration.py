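"""Vibration onset/offset recovery from the digital-stethoscope channel.

The capsule's 3-s vibrations appear on the abdominal stethoscope trace as
amplitude-ramped narrowband bursts.  Detection is a two-step procedure:

1. rectify the trace and low-pass it into a smooth amplitude envelope;
2. segment the envelope by least-squares piecewise-constant change-point
   detection (binary segmentation, split count steered by the expected
   number of vibrations), assemble events from runs of high-mean segments,
   and refine the edges to the envelope's threshold crossings.

A CSV override table replaces the study's manual inspect-and-adjust step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .channels import Channel

__all__ = ["VibrationEvent", "detect_vibrations", "apply_overrides", "envelope",
           "binseg_piecewise_constant", "assign_conditions"]


@dataclass
class VibrationEvent:
    onset: float
    offset: float
    condition: str | None = None
    confidence: float = 0.0
    source: str = "auto"       # auto | override | ground_truth
    valid: bool = True         # duration within tolerance of the expected value

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("event offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def envelope(x: np.ndarray, rate: float, cutoff_hz: float = 10.0,
             order: int = 4) -> np.ndarray:
    """Rectified, zero-phase low-passed amplitude envelope."""
    sos = signal.butter(order, cutoff_hz, "lowpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, np.abs(x))


def binseg_piecewise_constant(y: np.ndarray, max_splits: int,
                              min_size: int = 2, penalty: float | None = None) -> list[int]:
    """Change points of a piecewise-constant-mean fit by binary segmentation.

    Greedily introduces the split with the largest squared-error reduction
    until ``max_splits`` is reached or no split reduces the cost by more
    than ``penalty`` (default: sigma^2 * 2*log(n), a BIC-flavoured floor
    with sigma estimated from first differences).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * min_size:
        return []
    if penalty is None:
        sigma2 = np.median(np.abs(np.diff(y))) ** 2 / 0.4549 + 1e-12
        penalty = 2.0 * sigma2 * np.log(n)

    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost(a: int, b: int) -> float:
        s, q = c1[b] - c1[a], c2[b] - c2[a]
        return q - s * s / (b - a)

    def best_split(a: int, b: int):
        ks = np.arange(a + min_size, b - min_size + 1)
        if len(ks) == 0:
            return None, 0.0
        sl, sr = c1[ks] - c1[a], c1[b] - c1[ks]
        ql = (c2[ks] - c2[a]) - sl * sl / (ks - a)
        qr = (c2[b] - c2[ks]) - sr * sr / (b - ks)
        cost = ql + qr
        k = int(np.argmin(cost))
        return int(ks[k]), seg_cost(a, b) - float(cost[k])

    segments: list[tuple[int, int]] = [(0, n)]
    cands = {}
    cands[(0, n)] = best_split(0, n)
    splits: list[int] = []
    while len(splits) < max_splits:
        seg, (k, gain) = max(cands.items(), key=lambda kv: kv[1][1])
        if k is None or gain <= penalty:
            break
        a, b = seg
        del cands[seg]
        segments.remove(seg)
        segments += [(a, k), (k, b)]
        cands[(a, k)] = best_split(a, k)
        cands[(k, b)] = best_split(k, b)
        splits.append(k)
    return sorted(splits)


def _refine_edge(env: np.ndarray, idx: int, thr: float, direction: int,
                 limit: int) -> int:
    """Walk from a change point to the first envelope crossing of ``thr``."""
    n = len(env)
    i = idx
    if direction < 0:       # onset: walk back while still above threshold
        while i > max(0, idx - limit) and env[i - 1] > thr:
            i -= 1
    else:                   # offset: walk forward while still above threshold
        while i < min(n - 1, idx + limit) and env[i + 1] > thr:
            i += 1
    return i


def detect_vibrations(stetho: Channel, expected_count: int,
                      expected_duration: float = 3.0,
                      envelope_cutoff_hz: float = 10.0,
                      work_rate: float = 50.0,
                      duration_tol: float = 0.5) -> list[VibrationEvent]:
    """Recover vibration events from the stethoscope channel.

    Returns events sorted by onset; ``confidence`` is the envelope contrast
    between the burst and its surroundings.  Events whose duration deviates
    from ``expected_duration`` by more than ``duration_tol`` are flagged
    (``valid=False``), not dropped.
    """
    if stetho.rate < 250:
        raise ValueError("stethoscope rate must be at least 250 Hz")
    env_full = envelope(stetho.data, stetho.rate, envelope_cutoff_hz)
    step = max(1, int(round(stetho.rate / work_rate)))
    env = env_full[::step]
    rate = stetho.rate / step

    scale = np.percentile(env, 99)
    if scale <= 0 or np.ptp(env) < 1e-12 * (abs(env.mean()) + 1e-30):
        warnings.warn(f"detected 0 vibrations, expected {expected_count}: "
                      "flat stethoscope channel", stacklevel=2)
        return []

    splits = binseg_piecewise_constant(env, max_splits=2 * expected_count + 10,
                                       min_size=max(2, int(0.1 * rate)))
    bounds = [0] + splits + [len(env)]
    means = np.array([env[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    lengths = np.diff(bounds)
    lo, hi = means.min(), means.max()
    # noise floor: length-weighted median of segment means (vibrations occupy
    # a minority of the block), then a low threshold so the weaker of the two
    # burst intensities is still classified as high
    order = np.argsort(means)
    cum = np.cumsum(lengths[order])
    floor_global = float(means[order][np.searchsorted(cum, cum[-1] / 2)])
    env_spread = 1.4826 * np.median(np.abs(env - np.median(env)))
    if hi - floor_global < 8.0 * max(env_spread, 1e-30):
        # no segment stands out of the envelope noise: flat channel
        warnings.warn(f"detected 0 vibrations, expected {expected_count}: "
                      "no bursts rise above the envelope noise", stacklevel=2)
        return []
    thr = floor_global + 0.25 * (hi - floor_global)
    high = means > thr

    events: list[VibrationEvent] = []
    i = 0
    limit = int(2.0 * rate)
    while i < len(means):
        if high[i]:
            j = i
            while j + 1 < len(means) and high[j + 1]:
                j += 1
            a, b = bounds[i], bounds[j + 1]
            burst = float(np.mean(env[a:b]))
            edge_thr = floor_global + 0.1 * (burst - floor_global)
            a = _refine_edge(env, a, edge_thr, -1, limit)
            b = _refine_edge(env, min(b, len(env) - 1), edge_thr, +1, limit)
            # extrapolate the rising envelope back to the noise floor so the
            # onset lands at the start of the amplitude ramp, not partway up
            k = max(2, int(0.06 * rate))
            if a + k < len(env):
                slope = (env[a + k] - env[a]) / k
                if slope > 0:
                    a = max(0, a - int(round((env[a] - floor_global) / slope)))
            left = env[max(0, a - int(rate)):a]
            right = env[b:b + int(rate)]
            floor = float(np.mean(np.concatenate([left, right]))) if (len(left) + len(right)) else floor_global
            conf = (burst - floor) / (burst + floor + 1e-30)
            onset, offset = a / rate, b / rate
            if offset > onset:
                events.append(VibrationEvent(
                    onset=onset, offset=offset, confidence=conf,
                    valid=abs((offset - onset) - expected_duration) <= duration_tol))
            i = j + 1
        else:
            i += 1

    if len(events) < expected_count:
        warnings.warn(f"detected {len(events)} vibrations, expected {expected_count}; "
                      "returning partial list", stacklevel=2)
    events.sort(key=lambda e: e.onset)
    return events


def assign_conditions(events: list[VibrationEvent], blocks) -> list[VibrationEvent]:
    """Label each event with the condition of the block containing its onset."""
    out = []
    for ev in events:
        cond = None
        for b in blocks:
            if b.start <= ev.onset < b.stop:
                cond = b.label
                break
        out.append(replace(ev, condition=cond))
    return out


def apply_overrides(events: list[VibrationEvent], override_table: pd.DataFrame,
                    recording_duration: float | None = None) -> list[VibrationEvent]:
    """Apply a manual-correction table to a detected event list.

    The table has columns ``index, action, onset_s, offset_s`` with
    ``action`` in {shift, set, delete, add}: *shift* adds the given deltas
    to event ``index``, *set* replaces its times, *delete* removes it and
    *add* appends a new event (index ignored).
    """
    out: list[VibrationEvent | None] = list(events)
    for _, row in override_table.iterrows():
        action = str(row["action"]).lower()
        if action == "add":
            onset, offset = float(row["onset_s"]), float(row["offset_s"])
            _check_span(onset, offset, recording_duration)
            out.append(VibrationEvent(onset, offset, source="override"))
            continue
        idx = int(row["index"])
        if not 0 <= idx < len(events):
            raise ValueError(f"override references event {idx}, have {len(events)}")
        if action == "delete":
            out[idx] = None
        elif action in ("shift", "set"):
            ev = out[idx]
            if ev is None:
                raise ValueError(f"event {idx} already deleted")
            don = 0.0 if pd.isna(row["onset_s"]) else float(row["onset_s"])
            doff = 0.0 if pd.isna(row["offset_s"]) else float(row["offset_s"])
            if action == "shift":
                onset, offset = ev.onset + don, ev.offset + doff
            else:
                onset = ev.onset if pd.isna(row["onset_s"]) else don
                offset = ev.offset if pd.isna(row["offset_s"]) else doff
            _check_span(onset, offset, recording_duration)
            out[idx] = replace(ev, onset=onset, offset=offset, source="override")
        else:
            raise ValueError(f"unknown override action {action!r}")
    kept = [e for e in out if e is not None]
    kept.sort(key=lambda e: e.onset)
    return kept


def _check_span(onset: float, offset: float, duration: float | None) -> None:
    if offset <= onset:
        raise ValueError("override produces offset <= onset")
    if onset < 0 or (duration is not None and offset > duration):
        raise ValueError("override outside recording span")
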