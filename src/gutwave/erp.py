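"""EEG preprocessing, epoching, artifact rejection, and LPP quantification.

The continuous EEG is downsampled to 250 Hz, cleaned with a 4th-order
Butterworth band-rejection filter around the 60 Hz line frequency (1 Hz
bandwidth, 24 dB/octave) and an 8th-order 0.1-80 Hz Butterworth bandpass
(48 dB/octave), both applied forward-backward (zero phase, so effective
orders double).  Epochs span [-200, 3000) ms around vibration onset (800
samples), are baseline-corrected to the 200 ms pre-onset mean, referenced
to the averaged mastoids (TP9/TP10), and rejected by threshold rules:
a >50 uV sample-to-sample step, a >200 uV range within any 200 ms window,
or flat-lining (<0.5 uV range in 200 ms).  The late positive potential is
summarized as the 400-720 ms mean over the posterior channel group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .channels import Channel
from .montage import MASTOIDS, POSTERIOR_CHANNELS

__all__ = ["EpochSet", "ERP", "LPPMetrics", "preprocess", "rereference_mastoids",
           "epoch", "reject_artifacts", "average_erp", "lpp_metrics"]

log = logging.getLogger(__name__)

TARGET_RATE = 250.0
EPOCH_WINDOW = (-0.2, 3.0)
LPP_WINDOW = (0.4, 0.72)


@dataclass
class EpochSet:
    data: np.ndarray           # epochs x channels x time, µV, baseline-corrected
    times: np.ndarray          # s relative to vibration onset
    rate: float
    labels: list[str]
    meta: pd.DataFrame         # per-epoch: onset_s, condition, cls
    reject_mask: np.ndarray = field(default=None)   # True = rejected
    reject_reason: list = field(default_factory=list)
    n_skipped_edge: int = 0

    def __post_init__(self):
        if self.reject_mask is None:
            self.reject_mask = np.zeros(len(self.data), dtype=bool)
        if not self.reject_reason:
            self.reject_reason = [""] * len(self.data)

    @property
    def accepted(self) -> np.ndarray:
        return self.data[~self.reject_mask]

    def counts(self) -> dict:
        reasons = [r for r, m in zip(self.reject_reason, self.reject_mask) if m]
        out = {"extracted": len(self.data),
               "accepted": int((~self.reject_mask).sum()),
               "rejected": int(self.reject_mask.sum())}
        for r in ("step50", "range200", "flatline"):
            out[r] = sum(r in s for s in reasons)
        return out


@dataclass
class ERP:
    mean: np.ndarray           # channels x time, µV
    sem: np.ndarray
    n_epochs: int
    times: np.ndarray
    labels: list[str]
    condition: str | None = None
    reference: str = "average mastoids (TP9/TP10)"


@dataclass
class LPPMetrics:
    amplitude: float           # µV, time-mean over the LPP window of the channel-mean
    latency: float             # s, peak time of the cluster-average waveform
    window: tuple
    channels: tuple


def preprocess(eeg: Channel, notch_hz: float = 60.0, band=(0.1, 80.0)) -> Channel:
    """Downsample to 250 Hz and apply line-noise rejection + bandpass.

    Accepts 1-D or channels-x-time data at any rate >= 2*80 Hz.
    """
    if eeg.rate < 2 * band[1]:
        raise ValueError(f"input rate {eeg.rate} Hz is below 2x the bandpass edge")
    data = np.atleast_2d(eeg.data)
    if eeg.rate != TARGET_RATE:
        frac = Fraction(TARGET_RATE / eeg.rate).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    # 4th-order band-reject, 1 Hz wide (24 dB/octave): scipy band filters
    # double the design order, hence N=2
    sos_notch = signal.butter(2, [notch_hz - 0.5, notch_hz + 0.5], "bandstop",
                              fs=TARGET_RATE, output="sos")
    # 8th-order bandpass (48 dB/octave): N=4
    sos_band = signal.butter(4, band, "bandpass", fs=TARGET_RATE, output="sos")
    data = signal.sosfiltfilt(sos_notch, data, axis=-1)
    data = signal.sosfiltfilt(sos_band, data, axis=-1)
    if eeg.data.ndim == 1:
        data = data[0]
    return Channel(eeg.name, data, TARGET_RATE, eeg.units, eeg.labels, eeg.clock_offset)


def rereference_mastoids(eeg: Channel, mastoids=MASTOIDS) -> Channel:
    """Subtract the average of the mastoid channels from every channel."""
    if eeg.labels is None:
        raise ValueError("re-referencing requires labelled multichannel data")
    try:
        idx = [eeg.labels.index(m) for m in mastoids]
    except ValueError as e:
        raise ValueError(f"mastoid channel missing: {e}") from None
    ref = eeg.data[idx].mean(axis=0)
    return Channel(eeg.name, eeg.data - ref, eeg.rate, eeg.units, list(eeg.labels),
                   eeg.clock_offset)


def epoch(eeg: Channel, events, window: tuple = EPOCH_WINDOW,
          class_filter: str | None = None) -> EpochSet:
    """Cut baseline-corrected epochs around event onsets.

    ``events`` rows need ``onset_s`` plus optional ``condition`` and ``cls``
    (true_positive / false_positive / miss); ``class_filter`` keeps only one
    class — the reference analysis epochs correctly detected vibrations
    (true positives) only.  The sample window is half-open, onset included:
    [-0.2, 3.0) s is exactly 800 samples at 250 Hz.  Events too close to
    the recording edge are skipped and counted.
    """
    data = np.atleast_2d(eeg.data)
    rate = eeg.rate
    i_lo = int(round(window[0] * rate))
    n_samp = int(round((window[1] - window[0]) * rate))
    n_base = -i_lo
    times = (np.arange(n_samp) + i_lo) / rate

    rows, cut = [], []
    skipped = 0
    for ev in _iter_events(events):
        if class_filter is not None and ev.get("cls") != class_filter:
            continue
        i0 = int(round((ev["onset_s"] - eeg.clock_offset) * rate)) + i_lo
        if i0 < 0 or i0 + n_samp > data.shape[-1]:
            skipped += 1
            continue
        cut.append(data[:, i0:i0 + n_samp])
        rows.append((ev["onset_s"], ev.get("condition"), ev.get("cls")))
    if skipped:
        log.info("epoch: skipped %d events too close to the recording edge", skipped)

    arr = np.stack(cut) if cut else np.empty((0, data.shape[0], n_samp))
    if len(arr):
        base = arr[:, :, :n_base].mean(axis=2, keepdims=True)
        arr = arr - base
    meta = pd.DataFrame(rows, columns=["onset_s", "condition", "cls"])
    return EpochSet(arr, times, rate, list(eeg.labels or []), meta,
                    n_skipped_edge=skipped)


def reject_artifacts(epochs: EpochSet, step_uv: float = 50.0,
                     range_uv: float = 200.0, flat_uv: float = 0.5,
                     window_s: float = 0.2) -> EpochSet:
    """Flag epochs by the threshold rules; flagged epochs leave all averages."""
    w = int(round(window_s * epochs.rate))
    mask = epochs.reject_mask.copy()
    reasons = list(epochs.reject_reason)
    for e in range(len(epochs.data)):
        x = epochs.data[e]
        tags = []
        if np.abs(np.diff(x, axis=-1)).max(initial=0.0) > step_uv:
            tags.append("step50")
        if x.shape[-1] >= w:
            win = np.lib.stride_tricks.sliding_window_view(x, w, axis=-1)
            ptp = win.max(axis=-1) - win.min(axis=-1)
            if ptp.max() > range_uv:
                tags.append("range200")
            if ptp.min() < flat_uv:
                tags.append("flatline")
        if tags:
            mask[e] = True
            reasons[e] = "+".join(tags)
    return EpochSet(epochs.data, epochs.times, epochs.rate, epochs.labels,
                    epochs.meta, mask, reasons, epochs.n_skipped_edge)


def average_erp(epochs: EpochSet, condition: str | None = None) -> ERP:
    """Arithmetic mean and SEM over accepted epochs (SEM=0 for one epoch)."""
    keep = ~epochs.reject_mask
    if condition is not None:
        keep &= (epochs.meta["condition"] == condition).to_numpy()
    data = epochs.data[keep]
    if len(data) == 0:
        raise ValueError(f"no accepted epochs for condition {condition!r}")
    mean = data.mean(axis=0)
    sem = (data.std(axis=0, ddof=1) / np.sqrt(len(data))) if len(data) > 1 \
        else np.zeros_like(mean)
    return ERP(mean, sem, len(data), epochs.times, list(epochs.labels), condition)


def lpp_metrics(erp: ERP, window: tuple = LPP_WINDOW,
                channels=POSTERIOR_CHANNELS,
                latency_window: tuple | None = None) -> LPPMetrics:
    """LPP amplitude (window mean of the channel-mean waveform) and latency
    (peak time of that waveform within the search window, default = the
    LPP window)."""
    idx = [erp.labels.index(c) for c in channels]
    wave = erp.mean[idx].mean(axis=0)
    sel = (erp.times >= window[0]) & (erp.times < window[1])
    amplitude = float(wave[sel].mean())
    lw = latency_window or window
    lsel = (erp.times >= lw[0]) & (erp.times < lw[1])
    latency = float(erp.times[lsel][np.argmax(wave[lsel])])
    return LPPMetrics(amplitude, latency, tuple(window), tuple(channels))


def _iter_events(events):
    if isinstance(events, pd.DataFrame):
        for _, row in events.iterrows():
            yield row.to_dict()
    else:
        for ev in events:
            yield ev if isinstance(ev, dict) else {
                "onset_s": ev.onset, "condition": getattr(ev, "condition", None),
                "cls": getattr(ev, "cls", None)}
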