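"""Electrogastrogram rhythm quantification.

Per block: a Hann-tapered power spectrum with absolute band powers in the
gastric ranges — bradygastria 0.5-2.25 cpm, normogastria 2.5-3.5 cpm,
tachygastria 3.75-9.75 cpm, total 0.5-11 cpm — and the peak frequency
within the normogastric range; a zero-phase windowed-sinc FIR bandpass
around that peak followed by the Hilbert transform for instantaneous phase
and amplitude envelope; a cycle-regularity artifact decision tree (a cycle
is bad if its duration falls outside mean +/- SD of the block's
cycle-duration distribution or if its phase is non-monotonic); and a clean
power spectrum recomputed over the surviving segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .channels import Channel

__all__ = ["EGGSpectrum", "CycleTable", "egg_spectrum", "gastric_phase",
           "flag_artifact_cycles", "recompute_power_clean", "BANDS_CPM"]

BANDS_CPM = {
    "bradygastria": (0.5, 2.25),
    "normogastria": (2.5, 3.5),
    "tachygastria": (3.75, 9.75),
    "total": (0.5, 11.0),
}

MIN_BLOCK_S = 100.0  # at least ~5 gastric cycles


@dataclass
class EGGSpectrum:
    freq_cpm: np.ndarray
    power: np.ndarray          # µV² per bin (Hann-tapered periodogram)
    band_power: dict           # integrated power per gastric band
    peak_freq: float           # cpm, argmax within the normogastric range

    def __post_init__(self):
        if any(v < 0 for v in self.band_power.values()):
            raise ValueError("band powers must be non-negative")


@dataclass
class CycleTable:
    times: np.ndarray          # s, of the phase/envelope series
    phase: np.ndarray          # rad, wrapped analytic-signal phase
    envelope: np.ndarray       # µV amplitude envelope
    rate: float
    boundaries: np.ndarray     # s, upward zero-phase crossings
    durations: np.ndarray      # s per cycle
    flags: list | None = None  # per cycle: None | 'length_outlier' | 'nonmonotonic'
    filtered: np.ndarray | None = None


def _band_mask(freq_cpm, lo, hi):
    return (freq_cpm >= lo) & (freq_cpm <= hi)


def egg_spectrum(egg: Channel, span: tuple | None = None) -> EGGSpectrum:
    """Hann-tapered power spectrum and gastric band powers for one block.

    A single taper over the whole block: a 13-min block yields ~0.077 cpm
    frequency resolution.  Band powers are the summed per-bin power over
    each closed cpm range.
    """
    ch = egg.crop(*span) if span is not None else egg
    if ch.duration < MIN_BLOCK_S:
        raise ValueError(f"block too short for EGG spectral analysis "
                         f"({ch.duration:.0f} s < {MIN_BLOCK_S:.0f} s)")
    f, p = signal.periodogram(ch.data, fs=ch.rate, window="hann",
                              detrend="constant", scaling="density")
    df = f[1] - f[0]
    p = p * df          # µV² per bin; band sums integrate the density
    freq_cpm = f * 60.0
    keep = freq_cpm <= 30.0
    freq_cpm, p = freq_cpm[keep], p[keep]
    bands = {name: float(p[_band_mask(freq_cpm, lo, hi)].sum())
             for name, (lo, hi) in BANDS_CPM.items()}
    norm = _band_mask(freq_cpm, *BANDS_CPM["normogastria"])
    if not norm.any():
        raise ValueError("no frequency bins fall in the normogastric range")
    peak = float(freq_cpm[norm][np.argmax(p[norm])])
    return EGGSpectrum(freq_cpm, p, bands, peak)


def gastric_phase(egg: Channel, peak_freq: float, half_bw_cpm: float = 1.0,
                  work_rate: float = 10.0, span: tuple | None = None) -> CycleTable:
    """Instantaneous gastric phase and envelope around the peak frequency.

    The signal is decimated to ``work_rate`` Hz, bandpassed with a
    linear-phase windowed-sinc FIR (length = 3 cycles of the low cutoff,
    applied centered so the group delay cancels), and Hilbert-transformed.
    Cycle boundaries are successive upward zero crossings of the phase.
    """
    if not 0.5 <= peak_freq <= 11.0:
        raise ValueError("peak frequency must lie in the 0.5-11 cpm gastric range")
    ch = egg.crop(*span) if span is not None else egg
    x = ch.data.astype(float)
    if ch.rate > work_rate:
        frac = Fraction(work_rate / ch.rate).limit_denominator(10000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator)
        rate = ch.rate * frac.numerator / frac.denominator
    else:
        rate = ch.rate

    lo_hz = max(peak_freq - half_bw_cpm, 0.3) / 60.0
    hi_hz = min(peak_freq + half_bw_cpm, 11.0) / 60.0
    numtaps = int(round(3.0 / lo_hz * rate))
    numtaps += 1 - numtaps % 2   # odd length, exactly linear phase
    if numtaps > len(x):
        raise ValueError("FIR filter longer than the data block")
    taps = signal.firwin(numtaps, [lo_hz, hi_hz], pass_zero=False, fs=rate)
    # symmetric kernel + 'same' convolution = zero-phase application
    filt = signal.fftconvolve(x - x.mean(), taps, mode="same")

    analytic = signal.hilbert(filt)
    phase = np.angle(analytic)
    env = np.abs(analytic)
    times = np.arange(len(filt)) / rate + ch.clock_offset

    up = np.flatnonzero((phase[:-1] < 0) & (phase[1:] >= 0)
                        & (np.diff(phase) < np.pi)) + 1
    boundaries = times[up]
    durations = np.diff(boundaries)
    return CycleTable(times, phase, env, rate, boundaries, durations,
                      filtered=filt)


def flag_artifact_cycles(cycles: CycleTable) -> CycleTable:
    """Apply the cycle-regularity decision tree.

    A cycle is flagged ``length_outlier`` if its duration falls outside the
    closed interval [mean - SD, mean + SD] of the block's cycle-duration
    distribution (a deliberately strict regularity rule: boundary ties are
    kept), and ``nonmonotonic`` if its unwrapped phase decreases anywhere
    within the cycle.  Either flag marks the cycle as a bad interval.
    """
    if len(cycles.durations) < 3:
        raise ValueError("need at least 3 cycles to assess regularity")
    m = float(np.mean(cycles.durations))
    s = float(np.std(cycles.durations, ddof=1))
    flags: list = []
    for k, dur in enumerate(cycles.durations):
        flag = None
        if dur < m - s or dur > m + s:
            flag = "length_outlier"
        else:
            i0 = int(round((cycles.boundaries[k] - cycles.times[0]) * cycles.rate))
            i1 = int(round((cycles.boundaries[k + 1] - cycles.times[0]) * cycles.rate))
            seg = np.unwrap(cycles.phase[i0:i1 + 1])
            if len(seg) > 1 and np.any(np.diff(seg) < 0):
                flag = "nonmonotonic"
        flags.append(flag)
    return CycleTable(cycles.times, cycles.phase, cycles.envelope, cycles.rate,
                      cycles.boundaries, cycles.durations, flags, cycles.filtered)


def clean_segments(cycles: CycleTable) -> list[tuple[float, float]]:
    """Merge contiguous unflagged cycles into clean (start, stop) spans."""
    if cycles.flags is None:
        raise ValueError("run flag_artifact_cycles first")
    spans: list[list[float]] = []
    for k, flag in enumerate(cycles.flags):
        if flag is not None:
            continue
        a, b = cycles.boundaries[k], cycles.boundaries[k + 1]
        if spans and abs(spans[-1][1] - a) < 0.5 / cycles.rate:
            spans[-1][1] = b
        else:
            spans.append([a, b])
    return [tuple(s) for s in spans]


def recompute_power_clean(egg: Channel, cycles: CycleTable,
                          nfft: int | None = None) -> EGGSpectrum:
    """Spectrum over the artifact-free segments only.

    Each clean segment gets its own Hann taper and periodogram on a common
    zero-padded frequency grid; segment spectra are averaged weighted by
    segment duration.
    """
    spans = clean_segments(cycles)
    if not spans:
        raise ValueError("no clean segments remain after artifact flagging")
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(max(
            int(round((b - a) * egg.rate)) for a, b in spans))))
    acc = None
    wsum = 0.0
    for a, b in spans:
        seg = egg.crop(a, b).data
        if len(seg) < 8:
            continue
        f, p = signal.periodogram(seg, fs=egg.rate, window="hann",
                                  detrend="constant", scaling="density",
                                  nfft=nfft)
        w = len(seg) / egg.rate
        acc = p * w if acc is None else acc + p * w
        wsum += w
    if acc is None:
        raise ValueError("no clean segments remain after artifact flagging")
    p = acc / wsum * (f[1] - f[0])
    freq_cpm = f * 60.0
    keep = freq_cpm <= 30.0
    freq_cpm, p = freq_cpm[keep], p[keep]
    bands = {name: float(p[_band_mask(freq_cpm, lo, hi)].sum())
             for name, (lo, hi) in BANDS_CPM.items()}
    norm = _band_mask(freq_cpm, *BANDS_CPM["normogastria"])
    peak = float(freq_cpm[norm][np.argmax(p[norm])])
    return EGGSpectrum(freq_cpm, p, bands, peak)
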