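# Methods

This note documents the models and numerical choices behind `gutwave`: what
the synthetic generator emulates, how each analysis stage is defined, which
defaults matter, and what the passing tests do and do not establish about
real recordings.

## The recording model

A session is a set of named channels at heterogeneous rates — 31-channel
EEG (analyzed at 250 Hz), plus 1000 Hz EGG, ECG, skin conductance and
stethoscope — with a block annotation (a long resting *baseline* followed
by *normal* and *enhanced* stimulation blocks, counterbalanced). Vibrations
last 3 s with a 0.25 s amplitude ramp; the full protocol delivers 60
vibrations per 13-min block (57 in the enhanced block, where three
stimulations are missing by design of the reference protocol). Cross-device
clocks are modeled as a per-channel offset (`clock_offset`), the software
analogue of TTL synchronization; all event times are on the session clock.

## Synthetic sessions

The generator's purpose is *parameter recovery*: every planted quantity is
exported as ground truth so a downstream estimate can be compared to what
was actually simulated. Randomness flows from one integer seed through
named `SeedSequence` children (schedule, responder, and one per channel),
making output bit-identical for identical configurations.

* **Schedule.** Onsets are placed with a minimum 4-s gap between
  vibrations, a 5-s stimulus-free margin at block edges, and uniform random
  jitter distributed over the remaining slack — pseudorandom timing with
  guaranteed non-vibration intervals between trials.
* **Responder.** Per-condition hit probability and false-positive
  probability per non-vibration interval; response latencies are normal
  with the protocol's reported statistics (mean 1.06 s / SD 0.46 s normal,
  0.74 s / 0.28 s enhanced), truncated to the plausible press range.
  Default hit/FP rates (0.75/0.10 normal, 0.95/0.03 enhanced) are chosen so
  the implied normalized A′ sits near the reported group means (~2.5 and
  ~2.85).
* **EEG.** Per-channel 1/f background (default SD 5 µV) plus an 8–12 Hz
  alpha rhythm (2 µV). The gastric evoked potential is a unit template —
  half-sine rise from 400 to 600 ms, exponential decay (τ = 0.8 s) to 3 s —
  scaled per condition (defaults 3 µV normal / 6 µV enhanced on the eight
  posterior channels) and added **only to responded vibrations**, with 30%
  multiplicative trial-to-trial jitter. The single-trial amplitude variance
  is not constrained by any published value; 30% is an exposed guess.
  A truncated template (`lpp_end`) confines the deflection to an arbitrary
  window when a test needs a compact planted support.
* **ECG.** Beats come from an integrate-rate (IPFM) model: the
  instantaneous IBI is 60/HR(t) plus a sinusoidal respiratory modulation
  (depth 40 ms at 15 breaths/min by default), integrated so that rate
  changes act within the ongoing beat; per-beat Gaussian jitter (3 ms) is
  added afterwards. HR(t) is the per-block tonic level (70/73/74 bpm)
  plus a phasic increment (+2 bpm) during each vibration. The trace is a
  Gaussian R-wave train (σ = 8 ms) with a small S-dip and additive noise.
* **EGG.** A slowly amplitude-modulated sinusoid at 3 cpm (100 µV) in pink
  noise (15 µV).
* **SCR.** Tonic level + slope + very slow sine, plus driver impulses
  (condition-scaled, 0.05/0.15 µS, log-normal jitter, 1 s latency after
  vibration onset; ~1 spontaneous response/min) convolved with a unit-peak
  bi-exponential impulse response (rise 0.75 s, decay 2 s).
* **Stethoscope.** An 80 Hz carrier with the 0.25 s onset ramp, enhanced
  bursts 2× the normal amplitude, in white noise.

What the generator does **not** emulate: volume-conducted artifacts
(ocular, muscle, cardiac-field contamination of EEG), electrode drift and
motion, realistic scalp topography beyond the posterior group membership,
gastric frequency drift, and any coupling between modalities beyond the
shared schedule. Passing parameter-recovery tests therefore demonstrates
the correctness of the estimators under the stated statistical model, not
robustness to every artifact class of real data — the threshold rejection
rules and cycle decision tree are exercised on synthetic artifact
injections instead.

## Vibration detection

Two steps, replacing a semi-manual procedure: (1) rectified envelope
(zero-phase 4th-order Butterworth low-pass at 10 Hz), decimated to 50 Hz;
(2) least-squares piecewise-constant segmentation by greedy binary
segmentation, with the split budget tied to the expected vibration count
and a BIC-style penalty floor. Segments are classified against a
length-weighted-median noise floor (threshold: floor + 25% of the contrast
to the highest segment) so that normal-intensity bursts survive next to 2×
enhanced bursts; runs of high segments become events. Onsets are refined by
walking to the 10% contrast crossing and extrapolating the envelope rise
back to the floor, which lands at the start of the amplitude ramp
(±~30 ms at default SNR). Events whose duration strays more than 0.5 s
from the 3-s stimulus are flagged `valid=False`, never silently dropped; a
CSV override table (shift/set/delete/add) replaces manual adjustment.

## Behavioral scoring

A vibration trial spans onset to offset + grace (default 1 s, consistent
with the ~1 s mean response latency; the matching rule is a package
choice). Consecutive windows never overlap (truncated at the next onset).
Each vibration also contributes one complementary non-vibration trial — the
interval to the next trial window — giving matched trial counts. The first
press onset inside a window is the hit; latency is press onset minus
vibration onset (press releases are not used). Zero presses is a valid
non-responder (TP = FP = 0, latency absent); zero events is an error.
A′ is defined piecewise (closed form above the chance diagonal, point
reflection below, 0.5 on it), which makes the reflection identity
A′(TP,FP) + A′(FP,TP) = 1 exact and handles the degenerate corners. The
above-chance threshold is the smallest k with P(X ≥ k) < α for
X ~ Binomial(n, ½) computed from the exact tail — 70/120 and 67/114 at
α = .05 — with `n+1` returned as an "unattainable" sentinel when even a
perfect score is not significant.

## ERP pipeline

Order of operations: anti-aliased polyphase downsampling to 250 Hz →
60 Hz band-reject (59.5–60.5 Hz, 4th order) → 0.1–80 Hz bandpass (8th
order) → mastoid re-reference → epoching → baseline correction →
threshold rejection. Filters are applied forward–backward (zero phase);
the stated orders are the design orders, so effective attenuation doubles.
Epochs are half-open [−0.2, 3.0) s windows — exactly 800 samples at
250 Hz with the onset sample included — baseline-corrected to the mean of
[−0.2, 0). Only true-positive (responded) vibrations are epoched by
default. Rejection rules, per epoch and channel: any sample-to-sample step
> 50 µV; any 200 ms (50-sample) window with range > 200 µV; any 200 ms
window with range < 0.5 µV (flat-line). Counts are conserved
(accepted + rejected = extracted) and reasons recorded. Manual ICA-based
component rejection is deliberately out of scope — it is not reproducible
— and the threshold rules plus the generator's artifact-free background
stand in for it; a pluggable hook can be added where real data demand it.
The LPP metric is the 400–720 ms time-mean of the posterior-group channel
mean; "latency" is the peak time of that waveform within the same window
(an operational definition — no standard one exists for this deflection).
SEM of a single epoch is defined as 0. The 0.1 Hz high-pass costs about 2%
of LPP amplitude; recovery tests use a 10% tolerance, which absorbs it.

## Cluster-based permutation test

Unit of exchange: subject-level condition means (paired design), so the
null is a per-subject sign flip of the difference map — equivalent to
swapping condition labels within subject. Per (channel, time) point a
paired t is computed; sign flips leave the pointwise sum of squares
unchanged, so each permutation's t-map is a closed-form function of its
mean map, and permutations are evaluated in vectorized batches.
Suprathreshold points (two-tailed t at the cluster-forming α, default .05)
of like sign are clustered under temporal contiguity plus spatial channel
adjacency (run-based union-find); cluster mass is Σt; the null statistic is
the maximum |mass| over both polarities per permutation; p = (1 + #{null ≥
observed}) / (1 + n_perm), never zero. For n ≤ 16 subjects the full 2ⁿ
enumeration is available and the Monte Carlo p converges to it. Adjacency
comes from standard 10-20 coordinates normalized to head-radius units with
a 0.4 threshold; at that radius the posterior midline chain (Pz–POz–Oz–
O1/O2) is connected while frontal–occipital pairs are not, and isolated
channels trigger a warning rather than an error. The default 5000
permutations match the reference analysis; scaled-down runs in the test
suite use 200–1000.

## EGG analysis

Spectra are single Hann-tapered periodograms over the whole block (~0.077
cpm resolution for a 13-min block; minimum 100 s ≈ 5 gastric cycles), with
band powers integrated from the density spectrum in µV². Because a Hann
taper spreads a pure tone over its equivalent noise bandwidth (1.5 bins),
tonal band integrals can exceed the raw variance by up to that factor —
the documented "taper-corrected" Parseval bound. The peak frequency is the
argmax within normogastria (2.5–3.5 cpm). Phase extraction decimates to
10 Hz, applies a linear-phase windowed-sinc FIR (±1 cpm around the peak,
length = 3 cycles of the low cutoff, centered convolution so the group
delay cancels), then the Hilbert transform. Cycles run between successive
upward zero-phase crossings. The artifact decision tree flags a cycle if
its duration leaves the closed interval [mean − SD, mean + SD] of the
block's cycle-duration distribution, or if its unwrapped phase decreases
anywhere. The strict mean ± SD rule flags cycles even in near-perfect data
once durations vary at all — a deliberate, literal reading of the
regularity criterion; boundary ties are kept. Clean power is recomputed
per surviving segment (own Hann taper, common zero-padded grid,
duration-weighted average); all-flagged blocks raise an error.

## Peripheral physiology

* **R peaks:** 5–25 Hz bandpass, squaring, 150 ms integration, adaptive
  threshold with 250 ms refractory, peak refined to the raw-signal maximum.
* **IBI cleaning:** rolling-median (11 beats) ± 25% — a standard
  toolbox-family rule, since no explicit rule is published.
* **SDNN:** sample SD (n − 1) of clean IBIs. **pLF/pHF:** Welch spectrum of
  the 4 Hz cubic-resampled tachogram; LF 0.04–0.15 Hz, HF 0.15–0.4 Hz,
  conventional band edges; each reported as a fraction of LF + HF.
* **Tonic HR:** mean over non-overlapping 60-s windows of 60000/mean(IBI).
* **Phasic HR:** IBI-overlap-weighted instantaneous HR over [onset,
  onset+3) minus [onset−3, onset). Beat quantization attenuates a 3-s step
  by roughly one-sixth of the mean IBI ratio (≈ 14% at 70 bpm): the
  boundary IBIs blend pre- and post-onset rates. This is a property of any
  windowed discrete-beat estimator (beat counting behaves similarly), so
  recovery tests bracket the planted step by [δ·(1 − IBI/3), δ] rather
  than asserting exact equality. Pseudo-events — 60 onsets at 3-s spacing
  starting 120 s into the baseline — provide the stationary reference whose
  deltas center on zero.
* **Breathing rate:** per 60-s window, linear-detrended even-resampled
  tachogram, autocorrelation, first dominant peak within 6–30 breaths/min
  (normalized height ≥ 0.25) confirmed by an elevated harmonic at twice
  the lag; BR = 60/lag, averaged over qualifying windows; no qualifying
  window ⇒ absent value (this is what happens when respiratory sinus
  arrhythmia is absent).
* **Phasic SCR:** 20 Hz downsampling, 200 ms smoothing, linear detrend and
  0.02 Hz high-pass for tonic removal (odd-reflection padding; a 2-s
  settle-in guard at each end is zeroed), then regularized inverse
  filtering with the bi-exponential impulse response (rise 0.75 s, decay
  2 s, regularization 0.01 — canonical electrodermal constants, exposed in
  the call). The inverse is peak-calibrated: a unit-amplitude response maps
  to a unit driver peak, so driver values remain in µS, linearity is exact
  up to filtering, and the 0.01 µS floor is meaningful. Per event the
  maximum driver in the 3-s stimulation window is reported, zeroed below
  threshold.

## Group statistics

Outliers beyond ±3 SD of each (block, measure) cell are flagged in a
single pass (no re-iteration) and excluded. Paired contrasts: two-tailed
paired t with pairwise deletion, Cohen's d = mean(diff)/SD(diff),
Bonferroni multiplier supplied by the caller; a zero-variance nonzero
difference is reported as t = ±∞ with p = 0 by convention. The
brain–behavior association is a condition-controlled Spearman correlation:
rank both variables, residualize the ranks on the binary condition
indicator, correlate the residuals (t-approximation with df = n − 3, or a
condition-stratified permutation p). Linear mixed-effects modelling is
intentionally delegated: the package's contract is the tidy long-format
table (subject, block, measure, value, outlier) that any external engine
can consume.

## Pipeline, formats, determinism

`run_pipeline` executes simulate → detect → score → ERP → cluster → EGG →
periphysiology → statistics under stage toggles; any stage failure halts
with a stage-tagged error. Sessions are one HDF5 container
(`/channels/<name>/{data,rate,units}`, written with HDF5 timestamps
disabled) plus CSV event/press tables and JSON ground truth; BrainVision
triplets and EDF are read through MNE for real recordings, and a minimal
BrainVision writer exists for round-trip testing. Every report file embeds
the configuration hash (location-independent) and seed; two runs with the
same configuration and seed produce byte-identical bundles.

## Problem sizes used in the test suite

The suite runs on scaled sessions chosen as the smallest sizes at which
each property is still meaningfully exercised: 320/240/240 s blocks with
12 vibrations per condition for multi-channel end-to-end paths; 480 s
blocks with the full 60 trials per condition (20 subjects) for LPP
recovery and cluster sensitivity; 500 null simulations at 500 permutations
on 8 × 40 maps for error-rate calibration; 5-subject cohorts for the
headline-direction and determinism checks. Full-protocol durations
(30 + 13 + 13 min) remain the generator defaults.

## Known limitations

* The generator's spatial model is binary (posterior group vs. rest); no
  forward-modeled topography, so topographic plausibility of real data is
  untested here.
* The strict mean ± SD cycle rule flags ~1/3 of cycles on realistic
  noisy EGG; this matches its literal definition but means "clean"
  segments can be short.
* Phasic HR recovers an attenuated step (see above); comparisons between
  conditions are unaffected because the attenuation is common to all
  events.
* EDF reading is implemented but exercised only at the dispatch level in
  tests, as no EDF writer is available in the supported environment.
* ICA-style artifact decomposition is out of scope; only threshold rules
  are automated.
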