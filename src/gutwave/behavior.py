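"""Perceptual scoring of button presses against vibration events.

Each vibration defines a trial window from its onset to its offset plus a
grace period; a press onset inside the window is a hit, and the response
latency is press onset minus vibration onset.  The complementary intervals
between consecutive trial windows form one non-vibration trial per
vibration (matched counts), in which any press onset is a false positive.
Sensitivity is summarized by the nonparametric index A' computed from the
hit and false-positive rates,

    A' = 1/2 + (TP - FP)(1 + TP - FP) / (4 TP (1 - FP))    for TP >= FP,

with the symmetric reflection below chance, and normalized to [0, pi] via
2*arcsin(sqrt(A')).  Above-chance performance is judged against the exact
binomial tail (e.g. >=70 of 120 trials, or >=67 of 114 when three
vibrations are missing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ScoredBehavior", "score_block", "a_prime", "normalize_a_prime",
           "binomial_threshold"]


@dataclass
class ScoredBehavior:
    n_vib_trials: int
    n_nonvib_trials: int
    tp: float                  # hit rate in [0, 1]
    fp: float                  # false-positive rate in [0, 1]
    n_correct: int             # hits + correct rejections
    a_prime: float
    a_prime_norm: float        # radians in [0, pi]
    above_chance: bool
    latency_mean: float | None  # s; None when there were no hits
    latency_sd: float | None
    per_event: pd.DataFrame     # one row per trial: kind, onset, outcome, latency
    n_unscored_presses: int = 0


def a_prime(tp: float, fp: float) -> float:
    """Nonparametric sensitivity A' from hit and false-positive rates.

    Defined piecewise: the closed form above the chance diagonal, its
    point reflection below it, and exactly 0.5 on the diagonal (which also
    covers the otherwise-indeterminate corners TP=FP=0 and TP=FP=1).
    """
    if not (0.0 <= tp <= 1.0 and 0.0 <= fp <= 1.0):
        raise ValueError("TP and FP must lie in [0, 1]")
    if tp == fp:
        return 0.5
    if tp > fp:
        return 0.5 + (tp - fp) * (1.0 + tp - fp) / (4.0 * tp * (1.0 - fp))
    return 0.5 - (fp - tp) * (1.0 + fp - tp) / (4.0 * fp * (1.0 - tp))


def normalize_a_prime(a: float) -> float:
    """Map A' in [0, 1] to [0, pi] via 2*arcsin(sqrt(A'))."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("A' must lie in [0, 1]")
    return 2.0 * math.asin(math.sqrt(a))


def binomial_threshold(n_trials: int, chance: float = 0.5, alpha: float = 0.05) -> int:
    """Smallest k with P(X >= k) < alpha for X ~ Binomial(n_trials, chance).

    Exact tail sum, no normal approximation.  Returns ``n_trials + 1`` when
    even a perfect score is not significant (degenerate small n).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if not (0.0 < chance < 1.0 and 0.0 < alpha < 1.0):
        raise ValueError("chance and alpha must lie in (0, 1)")
    k = np.arange(n_trials + 2)
    tail = stats.binom.sf(k - 1, n_trials, chance)   # P(X >= k); k=n+1 gives 0
    hits = np.flatnonzero(tail < alpha)
    return int(hits[0])


def score_block(events, presses, block_span: tuple[float, float],
                grace: float = 1.0, alpha: float = 0.05) -> ScoredBehavior:
    """Score one block's presses against its vibration events.

    ``events`` is a sequence of objects or dicts with onset/offset times;
    ``presses`` is ``(press_times, release_times)`` or a sequence of press
    onset times.  Presses falling in no trial window are counted but not
    scored.  Zero presses is valid (a non-responder: TP=FP=0, latency
    absent); zero events is an error.
    """
    onsets, offsets = _event_times(events)
    if len(onsets) == 0:
        raise ValueError("cannot score a block with zero vibration events")
    t0, t1 = block_span
    if onsets.min() < t0 or offsets.max() > t1:
        raise ValueError("events extend outside the block span")
    press_t = _press_times(presses)
    press_t = press_t[(press_t >= t0) & (press_t < t1)]

    n = len(onsets)
    # vibration trial windows, truncated so consecutive windows never overlap
    win_lo = onsets
    win_hi = np.minimum(offsets + grace, np.append(onsets[1:], t1))

    rows = []
    used = np.zeros(len(press_t), dtype=bool)
    hits = 0
    latencies = []
    for i in range(n):
        inside = (press_t >= win_lo[i]) & (press_t < win_hi[i])
        if inside.any():
            first = press_t[inside][0]
            used |= inside
            hits += 1
            lat = first - onsets[i]
            latencies.append(lat)
            rows.append(("vibration", onsets[i], "hit", lat))
        else:
            rows.append(("vibration", onsets[i], "miss", np.nan))

    # one complementary non-vibration trial per vibration
    n_fp = 0
    for i in range(n):
        lo = win_hi[i]
        hi = onsets[i + 1] if i + 1 < n else t1
        inside = (press_t >= lo) & (press_t < hi)
        if inside.any():
            n_fp += 1
            used |= inside
            rows.append(("non-vibration", lo, "false_positive", np.nan))
        else:
            rows.append(("non-vibration", lo, "correct_rejection", np.nan))

    tp_rate = hits / n
    fp_rate = n_fp / n
    n_correct = hits + (n - n_fp)
    ap = a_prime(tp_rate, fp_rate)
    lat = np.asarray(latencies)
    return ScoredBehavior(
        n_vib_trials=n, n_nonvib_trials=n, tp=tp_rate, fp=fp_rate,
        n_correct=n_correct, a_prime=ap, a_prime_norm=normalize_a_prime(ap),
        above_chance=n_correct >= binomial_threshold(2 * n, 0.5, alpha),
        latency_mean=float(lat.mean()) if len(lat) else None,
        latency_sd=float(lat.std(ddof=1)) if len(lat) > 1 else (0.0 if len(lat) == 1 else None),
        per_event=pd.DataFrame(rows, columns=["kind", "onset_s", "outcome", "latency_s"]),
        n_unscored_presses=int((~used).sum()),
    )


def _event_times(events):
    onsets, offsets = [], []
    for ev in events:
        if isinstance(ev, dict):
            onsets.append(ev["onset_s"])
            offsets.append(ev["offset_s"])
        else:
            onsets.append(ev.onset)
            offsets.append(ev.offset)
    order = np.argsort(onsets)
    return np.asarray(onsets, float)[order], np.asarray(offsets, float)[order]


def _press_times(presses):
    if isinstance(presses, tuple) and len(presses) == 2:
        presses = presses[0]
    return np.sort(np.asarray(presses, dtype=float))
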