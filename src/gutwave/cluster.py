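"""Spatiotemporal cluster-based permutation test for paired ERP contrasts.

Given per-subject condition-mean maps (subjects x channels x time) for two
conditions of a paired design, the test (1) computes a paired t-value at
every (channel, time) point, (2) thresholds it two-tailed at the
cluster-forming alpha, (3) groups suprathreshold points of like sign into
clusters connected under spatial channel adjacency and temporal contiguity,
(4) scores each cluster by its mass (sum of member t-values), and (5)
compares observed masses against a Monte Carlo null built by randomly
exchanging condition labels within subject (equivalently, flipping the sign
of each subject's difference map) and recording the maximum cluster mass of
either polarity per permutation.  Cluster p-values use the +1-corrected
estimator p = (1 + #{null >= observed}) / (1 + n_perm), so p is never zero;
for small samples the full 2^n sign-flip null can be enumerated exactly.

Channel adjacency derives from standard 10-20 scalp coordinates with a
Euclidean distance threshold expressed in units of head radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .montage import EEG_CHANNELS, standard_positions

__all__ = ["Adjacency", "ClusterResult", "build_adjacency", "default_adjacency",
           "cluster_test"]


@dataclass
class Adjacency:
    labels: list[str]
    matrix: np.ndarray   # symmetric bool, zero diagonal

    def __post_init__(self):
        m = np.asarray(self.matrix, bool)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("adjacency matrix shape must match labels")
        if not np.array_equal(m, m.T) or m.diagonal().any():
            raise ValueError("adjacency must be symmetric with a zero diagonal")
        self.matrix = m
        isolated = [self.labels[i] for i in np.flatnonzero(~m.any(axis=1))]
        if isolated:
            warnings.warn(f"channels without neighbors: {isolated}", stacklevel=2)

    def neighbor_lists(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.matrix]


@dataclass
class Cluster:
    channels: np.ndarray       # member channel indices (one per member point)
    time_bins: np.ndarray      # member time-bin indices
    polarity: int              # +1 / -1
    mass: float                # sum of member t-values
    p: float = 1.0


@dataclass
class ClusterResult:
    clusters: list
    t_map: np.ndarray
    cluster_threshold: float
    n_permutations: int
    alpha: float
    seed: int | None
    labels: list[str] = field(default_factory=list)
    null_max_mass: np.ndarray | None = None

    def significant(self) -> list:
        return [c for c in self.clusters if c.p < self.alpha]

    def mask(self, significant_only: bool = True) -> np.ndarray:
        out = np.zeros_like(self.t_map, dtype=bool)
        for c in (self.significant() if significant_only else self.clusters):
            out[c.channels, c.time_bins] = True
        return out


def build_adjacency(montage: dict, max_dist: float, labels=None) -> Adjacency:
    """Neighbor matrix: channels are adjacent iff their Euclidean distance
    is <= ``max_dist`` (same units as the montage coordinates)."""
    labels = list(labels if labels is not None else montage.keys())
    missing = [c for c in labels if c not in montage]
    if missing:
        raise KeyError(f"channels absent from montage: {missing}")
    pts = np.array([montage[c] for c in labels], dtype=float)
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    mat = (d <= max_dist) & ~np.eye(len(labels), dtype=bool)
    return Adjacency(labels, mat)


def default_adjacency(labels=EEG_CHANNELS, max_dist: float = 0.4) -> Adjacency:
    """Adjacency on the standard montage, distances in head-radius units."""
    return build_adjacency(standard_positions(labels), max_dist, labels)


# --------------------------------------------------------------------------
# connected-component labelling over (channel, time) masks

def _label_clusters(mask: np.ndarray, neighbors: list[np.ndarray]):
    """Connected components of a boolean channel x time mask.

    Connectivity: temporal contiguity within a channel plus spatial
    adjacency between temporally overlapping suprathreshold runs.  Returns
    a list of (channel_idx_array, time_idx_array) pairs.
    """
    n_ch, n_t = mask.shape
    runs = []            # (channel, t_start, t_stop) half-open
    runs_by_ch: list[list[int]] = [[] for _ in range(n_ch)]
    for c in range(n_ch):
        row = mask[c]
        if not row.any():
            continue
        d = np.diff(row.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        stops = np.flatnonzero(d == -1) + 1
        if row[0]:
            starts = np.concatenate([[0], starts])
        if row[-1]:
            stops = np.concatenate([stops, [n_t]])
        for a, b in zip(starts, stops):
            runs_by_ch[c].append(len(runs))
            runs.append((c, int(a), int(b)))

    parent = list(range(len(runs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for c in range(n_ch):
        if not runs_by_ch[c]:
            continue
        for nb in neighbors[c]:
            if nb <= c or not runs_by_ch[nb]:
                continue
            ra, rb = runs_by_ch[c], runs_by_ch[nb]
            i = j = 0
            while i < len(ra) and j < len(rb):
                _, a0, a1 = runs[ra[i]]
                _, b0, b1 = runs[rb[j]]
                if a0 < b1 and b0 < a1:      # temporal overlap
                    union(ra[i], rb[j])
                if a1 <= b1:
                    i += 1
                else:
                    j += 1

    groups: dict[int, list[int]] = {}
    for i in range(len(runs)):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        chs, ts = [], []
        for i in members:
            c, a, b = runs[i]
            ts.append(np.arange(a, b))
            chs.append(np.full(b - a, c))
        out.append((np.concatenate(chs), np.concatenate(ts)))
    return out


def _t_from_means(mean: np.ndarray, ssq: np.ndarray, n: int) -> np.ndarray:
    """Paired t from per-point means of (possibly sign-flipped) differences.

    Sign flips leave the per-point sum of squares unchanged, so the t-map
    of any permutation is a function of its mean map alone.
    """
    var = (ssq - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def _max_cluster_mass(t_map: np.ndarray, thr: float, neighbors) -> float:
    best = 0.0
    for sign in (1, -1):
        for chs, ts in _label_clusters(sign * t_map > thr, neighbors):
            best = max(best, abs(float(t_map[chs, ts].sum())))
    return best


def cluster_test(cond_a: np.ndarray, cond_b: np.ndarray, adjacency: Adjacency,
                 n_perm: int = 5000, alpha: float = 0.05,
                 cf_alpha: float = 0.05, seed: int | None = None,
                 method: str = "montecarlo") -> ClusterResult:
    """Paired spatiotemporal cluster permutation test of A vs B.

    ``cond_a``/``cond_b``: subjects x channels x time condition means for
    the same subjects in the same order (>=2 subjects).  ``method`` is
    ``montecarlo`` (random sign flips, ``n_perm`` draws) or ``exact``
    (all 2^n sign patterns; feasible for small n).
    """
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have identical shapes "
                         "(same subjects in both conditions)")
    n, n_ch, n_t = a.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_ch != len(adjacency.labels):
        raise ValueError("channel count does not match adjacency")

    diffs = (a - b).reshape(n, n_ch * n_t)
    ssq = (diffs ** 2).sum(axis=0)
    t_obs = _t_from_means(diffs.mean(axis=0), ssq, n).reshape(n_ch, n_t)
    thr = float(stats.t.ppf(1.0 - cf_alpha / 2.0, n - 1))
    neighbors = adjacency.neighbor_lists()

    clusters: list[Cluster] = []
    for sign in (1, -1):
        for chs, ts in _label_clusters(sign * t_obs > thr, neighbors):
            clusters.append(Cluster(chs, ts, sign, float(t_obs[chs, ts].sum())))
    clusters.sort(key=lambda c: -abs(c.mass))

    if method == "exact":
        if n > 16:
            raise ValueError("exact enumeration is limited to n <= 16 subjects")
        signs = np.array([[1 if (m >> s) & 1 else -1 for s in range(n)]
                          for m in range(2 ** n)], dtype=float)
        n_eff = signs.shape[0]
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        n_eff = n_perm
    else:
        raise ValueError(f"unknown method {method!r}")

    null_max = np.empty(n_eff)
    batch = max(1, int(2e7 // max(diffs.size, 1)))
    for lo in range(0, n_eff, batch):
        s = signs[lo:lo + batch]
        means = s @ diffs / n
        t_batch = _t_from_means(means, ssq[None, :], n)
        for k in range(t_batch.shape[0]):
            null_max[lo + k] = _max_cluster_mass(
                t_batch[k].reshape(n_ch, n_t), thr, neighbors)

    for c in clusters:
        if method == "exact":
            c.p = float((null_max >= abs(c.mass)).mean())
        else:
            c.p = float((1 + (null_max >= abs(c.mass)).sum()) / (1 + n_eff))

    return ClusterResult(clusters, t_obs, thr, n_eff, alpha, seed,
                         list(adjacency.labels), null_max)
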