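"""Cardiac, respiratory, and electrodermal quantification.

* R-peak detection: 5-25 Hz bandpass, squaring, moving-window integration,
  adaptive-threshold peak picking with a 250 ms refractory period, with
  peak times refined to the raw-signal local maxima.
* Interbeat intervals (IBIs) cleaned by a rolling-median +/-25% rule; SDNN
  is the sample SD of the clean IBIs; pLF/pHF are relative band powers of
  the 4 Hz cubic-resampled tachogram (LF 0.04-0.15 Hz, HF 0.15-0.4 Hz).
* Tonic HR: mean over non-overlapping 60-s windows of 60000/mean(IBI).
* Phasic HR: per event, IBI-overlap-weighted instantaneous HR over the 3-s
  stimulation window minus the immediately preceding 3-s window; pseudo-
  events placed in the baseline block provide the no-stimulation reference.
* Breathing rate from the RSA rhythm of the tachogram: per 60-s window,
  linear detrend, autocorrelation, first dominant positive-lag peak within
  6-30 breaths/min with harmonic confirmation.
* Phasic SCR: 20 Hz downsampling, 200 ms smoothing, regularized
  deconvolution with a bi-exponential impulse response; per event the
  maximum phasic driver in the 3-s window, zeroed below 0.01 µS.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import interpolate, signal
from scipy.ndimage import uniform_filter1d

from .channels import Channel
from .synth import scr_impulse_response

__all__ = ["IBISeries", "detect_r_peaks", "clean_ibis", "sdnn", "plf_phf",
           "tonic_hr", "phasic_hr", "make_pseudo_events", "estimate_br",
           "phasic_scr", "deconvolve_scr"]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass
class IBISeries:
    r_peak_times: np.ndarray    # s
    ibis: np.ndarray            # ms, diff of r_peak_times
    outlier_mask: np.ndarray    # True = abnormal, excluded from statistics

    @property
    def clean(self) -> np.ndarray:
        return self.ibis[~self.outlier_mask]

    def crop(self, span: tuple) -> "IBISeries":
        t0, t1 = span
        keep = (self.r_peak_times >= t0) & (self.r_peak_times < t1)
        idx = np.flatnonzero(keep)
        if len(idx) < 2:
            return IBISeries(self.r_peak_times[keep], np.array([]),
                             np.array([], dtype=bool))
        sl = slice(idx[0], idx[-1])
        return IBISeries(self.r_peak_times[keep], self.ibis[sl],
                         self.outlier_mask[sl])


def detect_r_peaks(ecg: Channel, refractory_s: float = 0.25) -> np.ndarray:
    """R-wave peak times via filtered-energy thresholding."""
    if ecg.rate < 250:
        raise ValueError("ECG rate must be at least 250 Hz")
    x = ecg.data.astype(float)
    if np.ptp(x) == 0:
        return np.array([])
    sos = signal.butter(3, [5.0, 25.0], "bandpass", fs=ecg.rate, output="sos")
    f = signal.sosfiltfilt(sos, x)
    energy = f * f
    w = max(1, int(round(0.15 * ecg.rate)))
    integ = np.convolve(energy, np.ones(w) / w, mode="same")
    thr = 0.3 * np.percentile(integ, 99)
    if thr <= 0:
        return np.array([])
    cand, _ = signal.find_peaks(integ, height=thr,
                                distance=int(round(refractory_s * ecg.rate)))
    half = int(round(0.05 * ecg.rate))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)
    return peaks / ecg.rate + ecg.clock_offset


def clean_ibis(r_peak_times: np.ndarray, window: int = 11,
               tolerance: float = 0.25) -> IBISeries:
    """IBIs with a rolling-median outlier mask.

    An IBI is abnormal if it deviates from the rolling median of its
    ``window`` neighbours by more than ``tolerance`` (fractional).
    """
    r = np.asarray(r_peak_times, float)
    ibis = np.diff(r) * 1000.0
    if len(ibis) == 0:
        return IBISeries(r, ibis, np.array([], dtype=bool))
    med = pd.Series(ibis).rolling(window, center=True, min_periods=1).median().to_numpy()
    mask = np.abs(ibis - med) > tolerance * med
    return IBISeries(r, ibis, mask)


def sdnn(series: IBISeries) -> float:
    """Sample SD (ddof=1) of the clean IBIs, ms."""
    x = series.clean
    if len(x) < 2:
        raise ValueError("need at least 2 clean IBIs for SDNN")
    return float(np.std(x, ddof=1))


def _even_tachogram(series: IBISeries, fs: float = 4.0):
    """Clean IBI tachogram cubic-resampled onto an even grid."""
    keep = ~series.outlier_mask
    t = series.r_peak_times[1:][keep]
    v = series.ibis[keep]
    if len(t) < 4:
        return None, None
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    f = interpolate.interp1d(t, v, kind="cubic", assume_sorted=True)
    return grid, f(grid)


def plf_phf(series: IBISeries, fs: float = 4.0) -> tuple[float, float]:
    """Relative LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) tachogram power,
    each as a fraction of LF+HF."""
    grid, x = _even_tachogram(series, fs)
    if grid is None or grid[-1] - grid[0] < 120.0:
        raise ValueError("need at least 120 s of clean IBIs for pLF/pHF")
    nper = min(len(x), int(fs * 120))
    f, p = signal.welch(signal.detrend(x), fs=fs, nperseg=nper)
    lf = float(p[(f >= LF_BAND[0]) & (f < LF_BAND[1])].sum())
    hf = float(p[(f >= HF_BAND[0]) & (f < HF_BAND[1])].sum())
    tot = lf + hf
    if tot <= 0:
        raise ValueError("no LF/HF power in tachogram")
    return lf / tot, hf / tot


def tonic_hr(series: IBISeries, block_span: tuple) -> float:
    """Block HR: mean over non-overlapping 60-s windows of 60000/mean(IBI)."""
    t0, t1 = block_span
    if t1 - t0 < 60.0:
        raise ValueError("block must be at least 60 s for tonic HR")
    beat_t = series.r_peak_times[1:]
    vals = []
    for a in np.arange(t0, t1 - 59.999, 60.0):
        sel = (beat_t >= a) & (beat_t < a + 60.0) & ~series.outlier_mask
        if sel.sum() >= 2:
            vals.append(60000.0 / series.ibis[sel].mean())
    if not vals:
        raise ValueError("no usable 60-s windows in block")
    return float(np.mean(vals))


def _instant_hr(series: IBISeries, lo: float, hi: float) -> float:
    """IBI-overlap-weighted instantaneous HR (bpm) over [lo, hi)."""
    r = series.r_peak_times
    starts, stops = r[:-1], r[1:]
    ov = np.minimum(stops, hi) - np.maximum(starts, lo)
    w = np.where(~series.outlier_mask, np.maximum(ov, 0.0), 0.0)
    if w.sum() <= 0:
        return np.nan
    mean_ibi_s = float((w * series.ibis).sum() / w.sum()) / 1000.0
    return 60.0 / mean_ibi_s


def phasic_hr(series: IBISeries, events, window_s: float = 3.0) -> pd.DataFrame:
    """Per-event HR delta: stimulation window minus the preceding window.

    Events closer than ``window_s`` to the IBI series edges are skipped.
    Returns a frame with onset_s and delta_bpm.
    """
    if len(series.r_peak_times) < 3:
        raise ValueError("too few beats for phasic HR")
    t_lo = series.r_peak_times[0]
    t_hi = series.r_peak_times[-1]
    rows = []
    for ev in _onsets(events):
        if ev - window_s < t_lo or ev + window_s > t_hi:
            continue
        stim = _instant_hr(series, ev, ev + window_s)
        pre = _instant_hr(series, ev - window_s, ev)
        rows.append((ev, stim - pre))
    return pd.DataFrame(rows, columns=["onset_s", "delta_bpm"])


def make_pseudo_events(baseline_span: tuple, n: int = 60, spacing_s: float = 3.0,
                       skip_s: float = 120.0) -> list[dict]:
    """Pseudo-event onsets in the baseline block: ``n`` onsets at
    ``spacing_s`` intervals starting ``skip_s`` into the block (the early
    baseline is ignored to allow a physiological steady state)."""
    t0, t1 = baseline_span
    onsets = t0 + skip_s + np.arange(n) * spacing_s
    if len(onsets) and onsets[-1] + spacing_s > t1:
        raise ValueError("baseline too short for the requested pseudo-events")
    return [{"onset_s": float(t), "offset_s": float(t + spacing_s),
             "kind": "pseudo"} for t in onsets]


def estimate_br(series: IBISeries, block_span: tuple, fs: float = 4.0,
                band_bpm: tuple = (6.0, 30.0), min_peak: float = 0.25,
                window_s: float = 60.0) -> float:
    """Breathing rate (breaths/min) from the tachogram's RSA rhythm.

    Per 60-s window: even resampling, linear detrend, autocorrelation; the
    first dominant positive-lag peak inside the physiologic band whose
    harmonic (twice the lag) is also elevated gives BR = 60/lag.  Windows
    with no qualifying peak are skipped; NaN if none qualify.
    """
    t0, t1 = block_span
    if t1 - t0 < 2 * window_s:
        raise ValueError("block must be at least 120 s for BR estimation")
    sub = series.crop(block_span)
    grid, x = _even_tachogram(sub, fs)
    if grid is None:
        return np.nan
    vals = []
    n_win = int((grid[-1] - grid[0]) // window_s)
    m = int(window_s * fs)
    lag_lo, lag_hi = 60.0 / band_bpm[1], 60.0 / band_bpm[0]
    for k in range(n_win):
        seg = x[k * m:(k + 1) * m]
        seg = signal.detrend(seg)
        if np.std(seg) == 0:
            continue
        ac = np.correlate(seg, seg, mode="full")[m - 1:]
        ac = ac / ac[0]
        lags = np.arange(m) / fs
        sel = (lags >= lag_lo) & (lags <= lag_hi)
        pk, props = signal.find_peaks(np.where(sel, ac, -np.inf), height=min_peak)
        if len(pk) == 0:
            continue
        best = pk[np.argmax(props["peak_heights"])]
        lag = lags[best]
        # harmonic confirmation at twice the fundamental lag
        h = int(round(2 * best))
        if h + 2 >= m or ac[max(h - 2, 0):h + 3].max() < 0.5 * ac[best]:
            continue
        vals.append(60.0 / lag)
    return float(np.mean(vals)) if vals else np.nan


# --------------------------------------------------------------------------
# skin conductance

def deconvolve_scr(scr: Channel, irf_params: tuple = (0.75, 2.0),
                   work_rate: float = 20.0, smooth_s: float = 0.2,
                   reg: float = 0.01, highpass_hz: float = 0.02):
    """Phasic sudomotor driver estimate by regularized inverse filtering.

    Returns ``(times, driver, smoothed)`` at ``work_rate``; the driver is
    clipped to be non-negative.
    """
    if not np.all(np.isfinite(scr.data)):
        raise ValueError("SCR channel contains non-finite samples")
    x = scr.data.astype(float)
    if scr.rate != work_rate:
        frac = Fraction(work_rate / scr.rate).limit_denominator(10000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator,
                                 padtype="line")
    w = max(1, int(round(smooth_s * work_rate)))
    x = uniform_filter1d(x, w, mode="nearest")
    # odd-reflect pad by two high-pass time constants so the tonic-removal
    # and inverse-filter edge transients land in the padding, not the data
    pad = min(len(x) - 1, int(round(2.0 / highpass_hz * work_rate)))
    xp = np.concatenate([2 * x[0] - x[pad:0:-1], x, 2 * x[-1] - x[-2:-pad - 2:-1]])
    # remove level and slope first: the high-pass settle-in transient scales
    # with the residual, not with the full tonic offset
    xp = signal.detrend(xp, type="linear")
    sos = signal.butter(2, highpass_hz, "highpass", fs=work_rate, output="sos")
    phasic_in = signal.sosfiltfilt(sos, xp)

    h = scr_impulse_response(work_rate, *irf_params)
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(len(phasic_in) + len(h))))
    H = np.fft.rfft(h, nfft)
    inv = np.conj(H) / (np.abs(H) ** 2 + reg * np.max(np.abs(H)) ** 2)
    X = np.fft.rfft(phasic_in, nfft)
    driver = np.fft.irfft(X * inv, nfft)[pad:pad + n]
    # the padding joint still carries a curvature kink; the driver is
    # undefined inside this settle-in margin, so zero it out
    guard = min(n // 4, int(round(2.0 * work_rate)))
    if guard:
        driver[:guard] = 0.0
        driver[-guard:] = 0.0
    # calibrate: a unit-amplitude response deconvolved through the same
    # regularized inverse must yield a unit driver peak
    cal = np.fft.irfft(H * inv, nfft).max()
    if cal > 0:
        driver /= cal
    times = np.arange(n) / work_rate + scr.clock_offset
    return times, np.maximum(driver, 0.0), x


def phasic_scr(scr: Channel, events, window_s: float = 3.0,
               threshold_us: float = 0.01, **kwargs) -> pd.DataFrame:
    """Per-event maximum phasic SCR in the 3-s stimulation window.

    Values below ``threshold_us`` are recorded as 0.
    """
    times, driver, _ = deconvolve_scr(scr, **kwargs)
    rows = []
    for ev in _onsets(events):
        sel = (times >= ev) & (times < ev + window_s)
        if not sel.any():
            continue
        v = float(driver[sel].max())
        rows.append((ev, v if v >= threshold_us else 0.0))
    return pd.DataFrame(rows, columns=["onset_s", "max_scr_us"])


def _onsets(events):
    for ev in events:
        if isinstance(ev, dict):
            yield float(ev["onset_s"])
        elif hasattr(ev, "onset"):
            yield float(ev.onset)
        else:
            yield float(ev)
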