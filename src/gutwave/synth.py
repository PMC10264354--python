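"""Synthetic multi-modal session generator.

Emulates one experimental session of the vibrating-capsule protocol: a long
resting baseline followed by two 13-min stimulation blocks (normal and
enhanced intensity, counterbalanced), each delivering 3-s capsule vibrations
in pseudorandom order.  The generator emits every recorded channel with the
statistical structure the downstream analysis assumes, together with the
ground truth needed for parameter-recovery testing:

* 31-channel EEG carrying a parieto-occipital late positive potential (LPP)
  time-locked to *responded* vibrations, on top of 1/f + alpha background;
* ECG with R-R intervals set by a tonic per-block heart rate, a phasic
  heart-rate increment during vibrations, and respiratory sinus arrhythmia;
* a ~3 cycle-per-minute gastric slow wave (EGG) in pink noise;
* skin conductance as tonic drift plus driver impulses convolved with a
  bi-exponential impulse response;
* a digital-stethoscope trace with an amplitude-ramped narrowband burst at
  every vibration (larger for enhanced intensity);
* a simulated responder pressing/releasing a button with configurable
  per-condition hit and false-positive rates and latency distribution.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` children, so identical configurations produce
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .channels import Block, Channel, Recording
from .montage import EEG_CHANNELS, POSTERIOR_CHANNELS

__all__ = [
    "ResponderParams", "EffectParams", "SessionConfig", "GroundTruth",
    "SchedulingError", "simulate_session", "simulate_ecg", "simulate_scr",
    "lpp_template", "scr_impulse_response", "pink_noise",
]


class SchedulingError(ValueError):
    """A block is too short for the requested stimulation count."""


# --------------------------------------------------------------------------
# parameter containers

def _cond_dict(normal, enhanced):
    return {"normal": normal, "enhanced": enhanced}


@dataclass
class ResponderParams:
    """Behavioral model of the button-pressing participant.

    Latency defaults are the study conditions: mean response latency
    1.06 s (normal) / 0.74 s (enhanced) with within-subject SDs 0.46 / 0.28 s.
    Hit/false-positive defaults are chosen so the implied sensitivity matches
    the reported normalized A-prime of ~2.49 (normal) / ~2.84 (enhanced).
    """

    hit_rate: dict = field(default_factory=lambda: _cond_dict(0.75, 0.95))
    #: probability of a spurious press per non-vibration interval
    fp_rate: dict = field(default_factory=lambda: _cond_dict(0.10, 0.03))
    latency_mean: dict = field(default_factory=lambda: _cond_dict(1.06, 0.74))
    latency_sd: dict = field(default_factory=lambda: _cond_dict(0.46, 0.28))
    hold_mean: float = 2.0   # s, button hold duration
    hold_sd: float = 0.5

    def __post_init__(self):
        for d in (self.hit_rate, self.fp_rate):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("rates must be probabilities in [0, 1]")
        for v in self.latency_mean.values():
            if v <= 0:
                raise ValueError("latency_mean must be positive")


@dataclass
class EffectParams:
    """Planted physiological effect sizes (per condition where applicable)."""

    # EEG late positive potential, µV, on the posterior channel group
    lpp_amplitude: dict = field(default_factory=lambda: _cond_dict(3.0, 6.0))
    lpp_window: tuple = (0.4, 0.72)   # rise start .. nominal window end, s
    lpp_peak: float = 0.6             # s post-onset
    lpp_end: float = 3.0              # s; deflection decays out to stimulus end
    lpp_decay_tau: float = 0.8        # s
    lpp_trial_jitter: float = 0.30    # multiplicative trial-to-trial SD
    lpp_channels: tuple = POSTERIOR_CHANNELS
    eeg_noise_uv: float = 5.0         # 1/f background SD
    eeg_alpha_uv: float = 2.0         # 8-12 Hz rhythm SD
    # gastric slow wave
    egg_freq: float = 3.0             # cpm
    egg_amplitude_uv: float = 100.0
    egg_noise_uv: float = 15.0
    # cardiac
    tonic_hr: dict = field(default_factory=lambda: {"baseline": 70.0, "normal": 73.0, "enhanced": 74.0})
    phasic_hr_delta: dict = field(default_factory=lambda: _cond_dict(2.0, 2.0))  # bpm during the 3-s vibration
    br: float = 15.0                  # breaths/min, respiratory sinus arrhythmia frequency
    rsa_depth_ms: float = 40.0        # peak-to-mean IBI modulation
    ibi_jitter_ms: float = 3.0
    ecg_noise_mv: float = 0.02
    # electrodermal
    scr_amplitude: dict = field(default_factory=lambda: _cond_dict(0.05, 0.15))  # µS driver amplitude
    scr_latency: float = 1.0          # s from vibration onset to sudomotor driver
    scr_irf: tuple = (0.75, 2.0)      # rise/decay time constants, s
    scr_spontaneous_per_min: float = 1.0
    scr_noise_us: float = 0.003
    # stethoscope burst
    stetho_amplitude: dict = field(default_factory=lambda: _cond_dict(1.0, 2.0))  # a.u.
    stetho_carrier_hz: float = 80.0
    stetho_ramp: float = 0.25         # s amplitude ramp-up
    stetho_noise: float = 0.05

    def __post_init__(self):
        if not 0.5 <= self.egg_freq <= 11.0:
            raise ValueError("egg_freq must lie in the 0.5-11 cpm gastric range")
        for d in (self.lpp_amplitude, self.scr_amplitude, self.stetho_amplitude):
            for v in d.values():
                if v < 0:
                    raise ValueError("amplitudes must be non-negative")


@dataclass
class SessionConfig:
    """Full description of one synthetic session.

    The defaults are the study conditions: a 30-min baseline followed by two
    13-min stimulation blocks with 60 (normal) / 57 (enhanced) vibrations of
    3 s each; set ``enhanced_first`` to counterbalance the block order.
    """

    block_plan: list = field(default_factory=lambda: [
        ("baseline", 1800.0), ("normal", 780.0), ("enhanced", 780.0)])
    n_stims: dict = field(default_factory=lambda: _cond_dict(60, 57))
    stim_duration: float = 3.0
    ramp_duration: float = 0.25
    min_gap: float = 4.0          # s between vibration offset and next onset
    edge_margin: float = 5.0      # s kept stimulus-free at block edges
    enhanced_first: bool = False
    seed: int = 0
    rates: dict = field(default_factory=lambda: {
        "eeg": 250.0, "ecg": 1000.0, "egg": 1000.0, "scr": 1000.0, "stetho": 1000.0})
    channels: tuple = ("eeg", "ecg", "egg", "scr", "stetho")
    responder: ResponderParams = field(default_factory=ResponderParams)
    effects: EffectParams = field(default_factory=EffectParams)

    def __post_init__(self):
        for _, dur in self.block_plan:
            if dur <= 0:
                raise ValueError("block durations must be positive")
        if self.stim_duration <= 0 or self.ramp_duration <= 0:
            raise ValueError("durations must be positive")

    def ordered_blocks(self) -> list:
        plan = list(self.block_plan)
        if self.enhanced_first:
            labels = [b[0] for b in plan]
            if "normal" in labels and "enhanced" in labels:
                i, j = labels.index("normal"), labels.index("enhanced")
                plan[i], plan[j] = (("enhanced", plan[i][1]), ("normal", plan[j][1]))
        return plan


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    events: list                 # dicts: onset_s, offset_s, block, condition, kind
    responded: np.ndarray        # bool per event
    latency: np.ndarray          # s per event (nan for misses)
    lpp_trial_amp: np.ndarray    # µV per event (0 for misses)
    r_peak_times: np.ndarray
    scr_driver_times: np.ndarray
    scr_driver_amps: np.ndarray
    tonic_hr: dict
    br: float
    effects: EffectParams
    responder: ResponderParams

    def to_json(self, path) -> None:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, tuple):
                return list(v)
            return v
        out = {
            "events": self.events,
            "responded": self.responded.astype(int).tolist(),
            "latency": [None if np.isnan(x) else float(x) for x in self.latency],
            "lpp_trial_amp": self.lpp_trial_amp.tolist(),
            "r_peak_times": self.r_peak_times.tolist(),
            "scr_driver_times": self.scr_driver_times.tolist(),
            "scr_driver_amps": self.scr_driver_amps.tolist(),
            "tonic_hr": self.tonic_hr,
            "br": self.br,
            "effects": {k: _clean(v) for k, v in dataclasses.asdict(self.effects).items()},
            "responder": {k: _clean(v) for k, v in dataclasses.asdict(self.responder).items()},
        }
        with open(path, "w") as f:
            json.dump(out, f, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# signal primitives

def pink_noise(n: int, rng: np.random.Generator, sd: float = 1.0) -> np.ndarray:
    """1/f-power noise of length ``n`` scaled to standard deviation ``sd``."""
    if n < 2 or sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** -0.5
    x = np.fft.irfft(spec, n)
    x *= sd / x.std()
    return x


def lpp_template(times: np.ndarray, rise_start: float = 0.4, peak: float = 0.6,
                 end: float = 3.0, decay_tau: float = 0.8) -> np.ndarray:
    """Unit-peak LPP waveform: half-sine rise to the peak, exponential decay.

    The deflection emerges at ``rise_start``, peaks at ``peak`` and decays
    toward zero until ``end`` (with a short cosine taper when truncated
    early), matching a late positivity that emerges ~400 ms after vibration
    onset, peaks ~600 ms and lasts up to the 3-s stimulus duration.
    """
    t = np.asarray(times, dtype=float)
    y = np.zeros_like(t)
    rise = (t >= rise_start) & (t <= peak)
    y[rise] = np.sin(0.5 * np.pi * (t[rise] - rise_start) / (peak - rise_start))
    dec = (t > peak) & (t < end)
    y[dec] = np.exp(-(t[dec] - peak) / decay_tau)
    if end < 2.9:  # truncated template: taper the last 40 ms to zero
        taper = dec & (t > end - 0.04)
        y[taper] *= 0.5 * (1 + np.cos(np.pi * (t[taper] - (end - 0.04)) / 0.04))
    return y


def scr_impulse_response(rate: float, tau_rise: float = 0.75, tau_decay: float = 2.0,
                         duration: float | None = None) -> np.ndarray:
    """Unit-peak bi-exponential sudomotor impulse response."""
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("SCR impulse-response time constants must be positive")
    if duration is None:
        duration = 10.0 * tau_decay
    t = np.arange(int(round(duration * rate))) / rate
    h = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = h.max()
    if peak > 0:
        h /= peak
    return h


def _add_at_times(trace: np.ndarray, rate: float, times, template: np.ndarray,
                  amps=None) -> None:
    """Add ``amp * template`` into ``trace`` starting at each time (in place)."""
    n = trace.shape[-1]
    m = len(template)
    amps = np.ones(len(times)) if amps is None else np.asarray(amps, float)
    for t0, a in zip(times, amps):
        i = int(round(t0 * rate))
        if i >= n or i + m <= 0:
            continue
        lo, hi = max(i, 0), min(i + m, n)
        trace[..., lo:hi] += a * template[lo - i:hi - i]


# --------------------------------------------------------------------------
# scheduling and the responder

def _schedule_block(block: Block, n: int, stim: float, gap: float, margin: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Pseudorandom non-overlapping vibration onsets inside one block."""
    need = n * stim + max(n - 1, 0) * gap + 2 * margin
    if need > block.duration:
        raise SchedulingError(
            f"block {block.label!r} ({block.duration:.0f} s) too short for "
            f"{n} stimulations of {stim} s with {gap} s gaps")
    slack = block.duration - need
    extra = rng.random(n + 1)
    extra *= slack / extra.sum()
    onsets = block.start + margin + np.cumsum(extra[:-1]) + np.arange(n) * (stim + gap)
    return onsets


def _simulate_responder(events: list, blocks: list, cfg: SessionConfig,
                        rng: np.random.Generator):
    """Button presses for hits (with latency) and false positives."""
    rp = cfg.responder
    responded = np.zeros(len(events), dtype=bool)
    latency = np.full(len(events), np.nan)
    presses: list[tuple[float, float]] = []

    for i, ev in enumerate(events):
        cond = ev["condition"]
        if rng.random() < rp.hit_rate[cond]:
            responded[i] = True
            lat = float(np.clip(rng.normal(rp.latency_mean[cond], rp.latency_sd[cond]),
                                0.15, cfg.stim_duration + 0.8))
            latency[i] = lat
            hold = float(np.clip(rng.normal(rp.hold_mean, rp.hold_sd), 0.3, 6.0))
            presses.append((ev["onset_s"] + lat, ev["onset_s"] + lat + hold))

    # false positives: one Bernoulli draw per non-vibration interval
    grace = 1.0
    by_block: dict[str, list] = {}
    for ev in events:
        by_block.setdefault(ev["block"], []).append(ev)
    for b in blocks:
        evs = by_block.get(b.label, [])
        for j, ev in enumerate(evs):
            lo = ev["offset_s"] + grace
            hi = evs[j + 1]["onset_s"] if j + 1 < len(evs) else b.stop
            if hi - lo < 0.5:
                continue
            if rng.random() < rp.fp_rate[ev["condition"]]:
                t0 = rng.uniform(lo + 0.1, hi - 0.4)
                presses.append((t0, t0 + float(np.clip(rng.normal(0.8, 0.3), 0.2, hi - t0))))

    presses.sort()
    # enforce non-overlapping holds
    cleaned: list[list[float]] = []
    for t0, t1 in presses:
        if cleaned and t0 <= cleaned[-1][1]:
            cleaned[-1][1] = max(cleaned[-1][1], t1)
        else:
            cleaned.append([t0, t1])
    press_times = np.array([p[0] for p in cleaned])
    release_times = np.array([p[1] for p in cleaned])
    return responded, latency, press_times, release_times


# --------------------------------------------------------------------------
# standalone channel simulators

def simulate_ecg(hr_profile, rsa_depth_ms: float, br: float, rate: float,
                 seed=None, duration: float = 300.0, ibi_jitter_ms: float = 0.0,
                 noise_mv: float = 0.0, rng: np.random.Generator | None = None):
    """Synthetic ECG with detectable R-waves.

    ``hr_profile`` is either a scalar (bpm) or a callable ``t -> bpm``.
    R-R intervals are modulated sinusoidally at the breathing rate ``br``
    (respiratory sinus arrhythmia) with depth ``rsa_depth_ms``.

    Returns ``(channel, r_peak_times)``.
    """
    if not 6.0 <= br <= 30.0:
        raise ValueError("breathing rate must lie in 6-30 breaths/min")
    prof = hr_profile if callable(hr_profile) else (lambda t, v=float(hr_profile): v)
    if rng is None:
        rng = np.random.default_rng(seed)
    # integrate-rate (integral pulse frequency modulation) beat generation:
    # the instantaneous IBI is 60/HR(t) plus a sinusoidal respiratory
    # modulation; beats fall where the integrated instantaneous rate
    # crosses successive integers, so HR changes act within the ongoing beat
    grid_rate = 20.0
    tg = np.arange(0.0, duration, 1.0 / grid_rate)
    hr_g = np.fromiter((prof(t) for t in tg), dtype=float, count=len(tg))
    ibi_g = 60.0 / hr_g + (rsa_depth_ms / 1000.0) * np.sin(2 * np.pi * br / 60.0 * tg)
    if np.any(ibi_g <= 0.2):
        raise ValueError("RSA depth / HR profile produced a non-positive IBI")
    rate_g = 1.0 / ibi_g
    beats = np.concatenate([[0.0], np.cumsum((rate_g[1:] + rate_g[:-1]) / 2.0)]) / grid_rate
    n_beats = int(np.floor(beats[-1] - 0.5))
    r_times = np.interp(np.arange(n_beats) + 0.5, beats, tg) + 0.3
    if ibi_jitter_ms:
        ibis = np.diff(np.concatenate([[r_times[0]], r_times]))
        ibis[1:] += rng.normal(0.0, ibi_jitter_ms / 1000.0, len(ibis) - 1)
        r_times = np.cumsum(ibis)
    r_times = r_times[r_times < duration - 0.1]

    n = int(round(duration * rate))
    trace = np.zeros(n)
    tt = np.arange(int(round(0.08 * rate))) / rate - 0.04
    qrs = np.exp(-0.5 * (tt / 0.008) ** 2)          # R wave, sigma 8 ms
    qrs -= 0.15 * np.exp(-0.5 * ((tt - 0.025) / 0.015) ** 2)  # small S dip
    _add_at_times(trace, rate, r_times - 0.04, qrs)
    if noise_mv:
        trace += rng.normal(0.0, noise_mv, n)
    return Channel("ecg", trace, rate, "mV"), r_times


def simulate_scr(driver_times, driver_amps, irf_params=(0.75, 2.0),
                 drift=(2.0, -2e-5), rate: float = 1000.0, seed=None,
                 duration: float = 300.0, noise_us: float = 0.0,
                 rng: np.random.Generator | None = None) -> Channel:
    """Skin conductance = tonic drift + drivers * bi-exponential IRF + noise.

    ``drift`` is ``(level µS, slope µS/s)``.
    """
    driver_amps = np.asarray(driver_amps, dtype=float)
    if np.any(driver_amps < 0):
        raise ValueError("driver amplitudes must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    level, slope = drift
    trace = level + slope * t + 0.025 * level * np.sin(2 * np.pi * 0.003 * t)
    if len(driver_amps):
        impulses = np.zeros(n)
        idx = np.round(np.asarray(driver_times, float) * rate).astype(int)
        ok = (idx >= 0) & (idx < n)
        np.add.at(impulses, idx[ok], driver_amps[ok])
        h = scr_impulse_response(rate, *irf_params)
        trace += signal.fftconvolve(impulses, h)[:n]
    if noise_us:
        trace += rng.normal(0.0, noise_us, n)
    return Channel("scr", trace, rate, "uS")


# --------------------------------------------------------------------------
# full session

def simulate_session(config: SessionConfig):
    """Generate one complete session.

    Returns ``(recording, events, (press_times, release_times), ground_truth)``
    where ``events`` is a list of dicts with keys
    ``onset_s, offset_s, block, condition, kind``.
    """
    cfg = config
    fx = cfg.effects
    ss = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ("schedule", "responder", "eeg", "ecg", "egg", "scr", "stetho"), ss.spawn(7))}

    # block layout
    blocks, t0 = [], 0.0
    for label, dur in cfg.ordered_blocks():
        blocks.append(Block(label, t0, t0 + dur))
        t0 += dur
    total = t0

    # stimulus schedule
    events = []
    for b in blocks:
        if b.label not in cfg.n_stims:
            continue
        onsets = _schedule_block(b, cfg.n_stims[b.label], cfg.stim_duration,
                                 cfg.min_gap, cfg.edge_margin, streams["schedule"])
        for on in onsets:
            events.append({"onset_s": float(on), "offset_s": float(on + cfg.stim_duration),
                           "block": b.label, "condition": b.label, "kind": "vibration"})
    events.sort(key=lambda e: e["onset_s"])

    responded, latency, press_t, release_t = _simulate_responder(
        events, blocks, cfg, streams["responder"])

    rec = Recording(blocks=blocks)
    stim_windows = [(e["onset_s"], e["offset_s"], e["condition"]) for e in events]

    # ---- EEG ----------------------------------------------------------------
    lpp_amp = np.zeros(len(events))
    if "eeg" in cfg.channels:
        rate = cfg.rates["eeg"]
        n = int(round(total * rate))
        rng = streams["eeg"]
        data = np.empty((len(EEG_CHANNELS), n))
        sos_alpha = signal.butter(4, [8.0, 12.0], "bandpass", fs=rate, output="sos")
        for c in range(len(EEG_CHANNELS)):
            x = pink_noise(n, rng, fx.eeg_noise_uv)
            if fx.eeg_alpha_uv:
                a = signal.sosfiltfilt(sos_alpha, rng.standard_normal(n))
                x += a * (fx.eeg_alpha_uv / a.std())
            data[c] = x
        tmpl_t = np.arange(int(round(cfg.stim_duration * rate))) / rate
        tmpl = lpp_template(tmpl_t, fx.lpp_window[0], fx.lpp_peak, fx.lpp_end,
                            fx.lpp_decay_tau)
        rows = [EEG_CHANNELS.index(c) for c in fx.lpp_channels]
        for i, ev in enumerate(events):
            if not responded[i]:
                continue
            amp = fx.lpp_amplitude[ev["condition"]] * max(
                0.0, 1.0 + fx.lpp_trial_jitter * rng.standard_normal())
            lpp_amp[i] = amp
            j = int(round(ev["onset_s"] * rate))
            hi = min(j + len(tmpl), n)
            data[rows, j:hi] += amp * tmpl[:hi - j]
        rec.add(Channel("eeg", data, rate, "uV", labels=list(EEG_CHANNELS)))

    # ---- ECG ----------------------------------------------------------------
    r_times = np.array([])
    if "ecg" in cfg.channels:
        def hr_profile(t):
            hr = fx.tonic_hr["baseline"]
            for b in blocks:
                if b.start <= t < b.stop:
                    hr = fx.tonic_hr.get(b.label, hr)
                    break
            for on, off, cond in stim_windows:
                if on <= t < off:
                    hr += fx.phasic_hr_delta[cond]
                    break
            return hr

        ch, r_times = simulate_ecg(hr_profile, fx.rsa_depth_ms, fx.br,
                                   cfg.rates["ecg"], duration=total,
                                   ibi_jitter_ms=fx.ibi_jitter_ms,
                                   noise_mv=fx.ecg_noise_mv, rng=streams["ecg"])
        rec.add(ch)

    # ---- EGG ----------------------------------------------------------------
    if "egg" in cfg.channels:
        rate = cfg.rates["egg"]
        n = int(round(total * rate))
        rng = streams["egg"]
        t = np.arange(n) / rate
        phase0 = rng.uniform(0, 2 * np.pi)
        am = 1.0 + 0.1 * np.sin(2 * np.pi * 0.005 * t + rng.uniform(0, 2 * np.pi))
        x = fx.egg_amplitude_uv * am * np.sin(2 * np.pi * fx.egg_freq / 60.0 * t + phase0)
        x += pink_noise(n, rng, fx.egg_noise_uv)
        rec.add(Channel("egg", x, rate, "uV"))

    # ---- SCR ----------------------------------------------------------------
    drv_t, drv_a = [], []
    if "scr" in cfg.channels:
        rng = streams["scr"]
        for on, off, cond in stim_windows:
            amp = fx.scr_amplitude[cond]
            if amp > 0:
                drv_t.append(on + fx.scr_latency)
                drv_a.append(amp * float(np.exp(0.3 * rng.standard_normal())))
        n_spont = rng.poisson(fx.scr_spontaneous_per_min * total / 60.0)
        for _ in range(n_spont):
            drv_t.append(rng.uniform(0, total))
            drv_a.append(rng.exponential(0.03))
        order = np.argsort(drv_t)
        drv_t = np.asarray(drv_t)[order] if len(drv_t) else np.array([])
        drv_a = np.asarray(drv_a)[order] if len(drv_a) else np.array([])
        ch = simulate_scr(drv_t, drv_a, fx.scr_irf, rate=cfg.rates["scr"],
                          duration=total, noise_us=fx.scr_noise_us, rng=rng)
        rec.add(ch)

    # ---- stethoscope --------------------------------------------------------
    if "stetho" in cfg.channels:
        rate = cfg.rates["stetho"]
        n = int(round(total * rate))
        rng = streams["stetho"]
        x = rng.normal(0.0, fx.stetho_noise, n)
        tt = np.arange(int(round(cfg.stim_duration * rate))) / rate
        env = np.minimum(tt / cfg.ramp_duration, 1.0)
        down = tt > cfg.stim_duration - 0.05
        env[down] *= np.clip((cfg.stim_duration - tt[down]) / 0.05, 0.0, 1.0)
        for on, off, cond in stim_windows:
            carrier = np.sin(2 * np.pi * fx.stetho_carrier_hz * tt + rng.uniform(0, 2 * np.pi))
            _add_at_times(x, rate, [on], fx.stetho_amplitude[cond] * env * carrier)
        rec.add(Channel("stetho", x, rate, "au"))

    gt = GroundTruth(events=events, responded=responded, latency=latency,
                     lpp_trial_amp=lpp_amp, r_peak_times=r_times,
                     scr_driver_times=np.asarray(drv_t), scr_driver_amps=np.asarray(drv_a),
                     tonic_hr=dict(fx.tonic_hr), br=fx.br,
                     effects=fx, responder=cfg.responder)
    return rec, events, (press_t, release_t), gt
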