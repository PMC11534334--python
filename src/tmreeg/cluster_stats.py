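"""Cluster-based permutation tests over channel x frequency x time data,
plus t-tests with Cohen's d and Pearson correlations.

The test forms clusters of pointwise-suprathreshold t-values. Two points are
adjacent when they share a channel and are grid neighbours in frequency or
time, or when they share a frequency-time point on neighbouring channels. A
cluster must span at least ``min_chan`` distinct channels (the montage
neighbourhood guarantees those channels are adjacency-connected through the
cluster). The cluster statistic is the sum of t-values; positive and
negative clusters are tested separately against the permutation distribution
of the per-permutation maximum (minimum) cluster sum, each tail at alpha/2.
Monte-Carlo p-values are (b + 1) / (n_perm + 1).

Permutation scheme: condition-label sign flips for paired designs (full
enumeration when 2^n <= n_perm), group-label shuffles for unpaired designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats as sps

from .montage import adjacency_matrix

__all__ = [
    "Neighborhood",
    "Cluster",
    "ClusterResult",
    "cluster_permutation_test",
    "ttest_effsize",
    "pearson_correlation",
]


@dataclass
class Neighborhood:
    """Symmetric, irreflexive channel adjacency over a montage subset."""

    channels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.shape != (len(self.channels), len(self.channels)):
            raise ValueError("adjacency matrix shape mismatch")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(m)):
            raise ValueError("adjacency must be irreflexive")
        if len(self.channels) > 1 and not m.any(axis=1).all():
            raise ValueError("every channel needs at least one neighbour")
        self.matrix = m

    @classmethod
    def from_montage(cls, channels) -> "Neighborhood":
        channels = list(channels)
        return cls(channels, adjacency_matrix(channels))

    def neighbor_lists(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.matrix[i]) for i in range(len(self.channels))]


@dataclass
class Cluster:
    """One suprathreshold cluster: member points, channel span, summed t, p."""

    points: np.ndarray  # (n_points, 3) int indices into (channel, freq, time)
    channels: frozenset[str]
    stat: float
    p: float
    polarity: int  # +1 or -1


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_obs: np.ndarray  # (n_ch, n_f, n_t)
    n_perm: int
    point_threshold: float
    channel_labels: list[str] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        """Clusters significant at the two-tailed level (alpha/2 per tail)."""
        return [c for c in self.clusters if c.p < alpha / 2.0]


def _as_4d(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:  # (subjects, channels)
        return data[:, :, None, None]
    if data.ndim == 3:  # (subjects, channels, times)
        return data[:, :, None, :]
    if data.ndim == 4:
        return data
    raise ValueError("data must be (subjects, channels[, freqs][, times])")


def _paired_t(d: np.ndarray) -> np.ndarray:
    """Dependent-sample t over axis 0; zero-variance points give t=0."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def _unpaired_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Independent-sample pooled-variance t; zero-variance points give t=0."""
    n1, n2 = a.shape[0], b.shape[0]
    v1 = a.var(axis=0, ddof=1)
    v2 = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t[~np.isfinite(t)] = 0.0
    return t


def _find_clusters(t: np.ndarray, threshold: float, neighbor_lists,
                   min_chan: int) -> tuple[list[np.ndarray], list[float], list[int]]:
    """Connected components of |t| > threshold, split by sign.

    Returns (member index arrays, cluster sums, polarities) for clusters
    spanning >= min_chan distinct channels.
    """
    members, sums, polarities = [], [], []
    for sign in (+1, -1):
        mask = (sign * t) > threshold
        if not mask.any():
            continue
        visited = np.zeros_like(mask)
        n_ch, n_f, n_t = mask.shape
        for c0, f0, t0 in np.argwhere(mask):
            if visited[c0, f0, t0]:
                continue
            stack = [(c0, f0, t0)]
            visited[c0, f0, t0] = True
            comp = []
            while stack:
                c, f, ti = stack.pop()
                comp.append((c, f, ti))
                if f > 0 and mask[c, f - 1, ti] and not visited[c, f - 1, ti]:
                    visited[c, f - 1, ti] = True
                    stack.append((c, f - 1, ti))
                if f + 1 < n_f and mask[c, f + 1, ti] and not visited[c, f + 1, ti]:
                    visited[c, f + 1, ti] = True
                    stack.append((c, f + 1, ti))
                if ti > 0 and mask[c, f, ti - 1] and not visited[c, f, ti - 1]:
                    visited[c, f, ti - 1] = True
                    stack.append((c, f, ti - 1))
                if ti + 1 < n_t and mask[c, f, ti + 1] and not visited[c, f, ti + 1]:
                    visited[c, f, ti + 1] = True
                    stack.append((c, f, ti + 1))
                for nc in neighbor_lists[c]:
                    if mask[nc, f, ti] and not visited[nc, f, ti]:
                        visited[nc, f, ti] = True
                        stack.append((nc, f, ti))
            comp = np.asarray(comp)
            if len(set(comp[:, 0])) < min_chan:
                continue
            members.append(comp)
            sums.append(float(t[comp[:, 0], comp[:, 1], comp[:, 2]].sum()))
            polarities.append(sign)
    return members, sums, polarities


def _max_cluster_sums(t: np.ndarray, threshold: float, neighbor_lists,
                      min_chan: int) -> tuple[float, float]:
    """Per-permutation maximum positive and minimum negative cluster sums."""
    _, sums, pols = _find_clusters(t, threshold, neighbor_lists, min_chan)
    pos = [s for s, p in zip(sums, pols) if p > 0]
    neg = [s for s, p in zip(sums, pols) if p < 0]
    return (max(pos) if pos else 0.0, min(neg) if neg else 0.0)


def cluster_permutation_test(data_a: np.ndarray, data_b: np.ndarray, paired: bool,
                             neighborhood: Neighborhood, n_perm: int = 1000,
                             cluster_alpha: float = 0.05, min_chan: int = 2,
                             seed: int | None = None) -> ClusterResult:
    """Cluster-based permutation test between two condition/group datasets.

    ``data_a`` and ``data_b`` are (subjects, channels[, freqs][, times])
    arrays; paired designs need equal subject counts in matching order.
    ``cluster_alpha`` is the two-tailed pointwise cluster-forming alpha.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    a, b = _as_4d(data_a), _as_4d(data_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("data_a and data_b must match in channels/freqs/times")
    if a.shape[1] != len(neighborhood.channels):
        raise ValueError("channel axis does not match the neighbourhood")
    nbr = neighborhood.neighbor_lists()
    rng = np.random.default_rng(seed)

    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired test needs equal subject counts")
        d = a - b
        n = d.shape[0]
        df = n - 1
        t_crit = float(sps.t.ppf(1 - cluster_alpha / 2, df))
        t_obs = _paired_t(d)
        members, sums, pols = _find_clusters(t_obs, t_crit, nbr, min_chan)
        # permutation distribution by condition-label sign flips
        if 2 ** n <= n_perm:
            flips = np.array(list(product((1.0, -1.0), repeat=n)))
        else:
            flips = rng.choice([1.0, -1.0], size=(n_perm, n))
        max_pos = np.empty(len(flips))
        min_neg = np.empty(len(flips))
        for i, s in enumerate(flips):
            t_p = _paired_t(d * s[:, None, None, None])
            max_pos[i], min_neg[i] = _max_cluster_sums(t_p, t_crit, nbr, min_chan)
        n_eff = len(flips)
    else:
        pooled = np.concatenate([a, b], axis=0)
        n1 = a.shape[0]
        df = pooled.shape[0] - 2
        t_crit = float(sps.t.ppf(1 - cluster_alpha / 2, df))
        t_obs = _unpaired_t(a, b)
        members, sums, pols = _find_clusters(t_obs, t_crit, nbr, min_chan)
        max_pos = np.empty(n_perm)
        min_neg = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            t_p = _unpaired_t(pooled[perm[:n1]], pooled[perm[n1:]])
            max_pos[i], min_neg[i] = _max_cluster_sums(t_p, t_crit, nbr, min_chan)
        n_eff = n_perm

    clusters = []
    for comp, s, pol in zip(members, sums, pols):
        if pol > 0:
            bcount = int((max_pos >= s).sum())
        else:
            bcount = int((min_neg <= s).sum())
        p = (bcount + 1) / (n_eff + 1)
        chans = frozenset(neighborhood.channels[c] for c in set(comp[:, 0]))
        clusters.append(Cluster(comp, chans, s, p, pol))
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(clusters, t_obs, n_eff, t_crit, list(neighborhood.channels))


def ttest_effsize(x, y, paired: bool) -> tuple[float, int, float, float]:
    """t statistic, degrees of freedom, two-tailed p, and Cohen's d.

    Paired: d = mean(x - y) / SD(x - y). Unpaired: pooled-SD d.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per sample")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal lengths")
        diff = x - y
        sd = diff.std(ddof=1)
        if sd == 0:
            if np.allclose(diff, 0):
                return 0.0, len(x) - 1, 1.0, 0.0
            raise ValueError("zero variance of the differences")
        res = sps.ttest_rel(x, y)
        d = float(diff.mean() / sd)
        return float(res.statistic), len(x) - 1, float(res.pvalue), d
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    sp2 = ((len(x) - 1) * v1 + (len(y) - 1) * v2) / (len(x) + len(y) - 2)
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0, len(x) + len(y) - 2, 1.0, 0.0
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(x, y)
    d = float((x.mean() - y.mean()) / np.sqrt(sp2))
    return float(res.statistic), len(x) + len(y) - 2, float(res.pvalue), d


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
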