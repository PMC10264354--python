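"""Group-level statistics on per-subject, per-block measure tables.

Measures live in a tidy table with one row per (subject, block, measure).
Outliers beyond +/-3 SD of each (block, measure) cell are flagged in a
single pass and excluded from statistics.  Paired block contrasts use the
two-tailed paired t-test with Cohen's d = mean(diff)/SD(diff) and a
caller-supplied Bonferroni family size.  Brain-behavior associations use a
condition-controlled Spearman correlation: both variables are rank
transformed, the ranks are residualized on the condition indicator, and
the residuals are correlated (with an optional condition-stratified
permutation p-value).  Linear mixed-effects modelling is delegated to an
external statistics engine; this module's contract is the long-format
table it exports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["flag_outliers", "paired_contrast", "partial_spearman",
           "ContrastResult", "make_measure_table"]


@dataclass
class ContrastResult:
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    cohen_d: float
    n_pairs: int


def make_measure_table(rows) -> pd.DataFrame:
    """Long-format table: columns subject, block, measure, value, outlier."""
    df = pd.DataFrame(rows, columns=["subject", "block", "measure", "value"])
    df["outlier"] = False
    dup = df.duplicated(["subject", "block", "measure"])
    if dup.any():
        raise ValueError("duplicate (subject, block, measure) rows")
    return df


def flag_outliers(table: pd.DataFrame, measure: str | None = None,
                  n_sd: float = 3.0) -> pd.DataFrame:
    """Flag values beyond ``n_sd`` SDs of their (block, measure) cell mean.

    Single pass: the mean/SD are computed once from all values, not
    re-iterated after exclusion.  Cells with fewer than 3 values are left
    unflagged with a warning.
    """
    out = table.copy()
    sel = slice(None) if measure is None else (out["measure"] == measure)
    sub = out.loc[sel] if measure is not None else out
    for (blk, meas), grp in sub.groupby(["block", "measure"]):
        v = grp["value"].to_numpy(float)
        if len(v) < 3:
            warnings.warn(f"({blk}, {meas}): only {len(v)} values, outlier "
                          "flagging skipped", stacklevel=2)
            continue
        m, s = v.mean(), v.std(ddof=1)
        if s == 0:
            continue
        flags = np.abs(v - m) > n_sd * s
        out.loc[grp.index[flags], "outlier"] = True
    return out


def paired_contrast(table: pd.DataFrame, measure: str, block_a: str,
                    block_b: str, bonferroni_family: int = 1) -> ContrastResult:
    """Two-tailed paired t-test of ``measure`` between two blocks.

    Subjects missing either block (or flagged as outliers) are dropped
    pairwise.  A zero-variance difference yields t = +/-inf with p = 0 (and
    p = 1 when the difference is identically zero).
    """
    sub = table[(table["measure"] == measure) & ~table["outlier"]]
    wide = sub.pivot(index="subject", columns="block", values="value")
    if block_a not in wide or block_b not in wide:
        raise ValueError(f"blocks {block_a!r}/{block_b!r} not present for {measure!r}")
    wide = wide[[block_a, block_b]].dropna()
    n = len(wide)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    diff = wide[block_a].to_numpy() - wide[block_b].to_numpy()
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            t, p, d = 0.0, 1.0, 0.0
        else:
            t = np.inf if diff.mean() > 0 else -np.inf
            p, d = 0.0, np.sign(diff.mean()) * np.inf
    else:
        t, p = sps.ttest_rel(wide[block_a], wide[block_b])
        d = diff.mean() / sd
    return ContrastResult(float(t), n - 1, float(p),
                          float(min(1.0, p * bonferroni_family)), float(d), n)


def partial_spearman(x, y, condition_labels, method: str = "approx",
                     n_perm: int = 5000, seed: int | None = None):
    """Spearman correlation of x and y controlling for a binary condition.

    Ranks of x and y are residualized on the condition indicator before
    correlating.  ``method='approx'`` gives the t-approximation p-value
    (df = n - 3, one covariate); ``method='permutation'`` shuffles y's
    residuals within condition strata.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cond = np.asarray(condition_labels)
    if not (len(x) == len(y) == len(cond)):
        raise ValueError("x, y and condition_labels must have equal lengths")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    levels = np.unique(cond)
    if len(levels) != 2:
        raise ValueError("condition must be binary")
    z = (cond == levels[1]).astype(float)

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    design = np.column_stack([np.ones(n), z])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    if denom == 0:
        return 0.0, 1.0
    rho = float((ex * ey).sum() / denom)

    if method == "approx":
        df = n - 3
        rr = min(abs(rho), 1.0 - 1e-15)
        t = rr * np.sqrt(df / (1.0 - rr ** 2))
        p = 2.0 * sps.t.sf(t, df)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        idx_by_level = [np.flatnonzero(z == v) for v in (0.0, 1.0)]
        for _ in range(n_perm):
            perm = np.arange(n)
            for idx in idx_by_level:
                perm[idx] = rng.permutation(idx)
            r = float((ex * ey[perm]).sum() / denom)
            if abs(r) >= abs(rho):
                count += 1
        p = (1 + count) / (1 + n_perm)
    else:
        raise ValueError(f"unknown method {method!r}")
    return rho, float(p)
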