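"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive -- exhaustive scans, hand-rolled
rank arithmetic, permutation resampling -- and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import chi2


def isodata_fixed_partitions(values: np.ndarray) -> list[np.ndarray]:
    """All ISODATA fixed-point partitions of integer-valued data.

    Scans every integer candidate threshold c: the partition at c is a
    fixed point when the midpoint of the two class means induces the
    same partition again.  Returns the boolean low-class membership
    arrays of every fixed partition found.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    fixed = []
    for c in range(int(x.min()), int(x.max()) + 1):
        low = x <= c
        if low.all() or not low.any():
            continue
        mid = 0.5 * (x[low].mean() + x[~low].mean())
        if np.array_equal(x <= mid, low):
            if not any(np.array_equal(low, f) for f in fixed):
                fixed.append(low)
    return fixed


def isodata_iterate(values: np.ndarray, max_iter: int = 10_000) -> float:
    """Direct iteration of the threshold recurrence from the global mean."""
    x = np.asarray(values, dtype=np.float64).ravel()
    t = x.mean()
    for _ in range(max_iter):
        low = x[x <= t]
        high = x[x > t]
        if low.size == 0 or high.size == 0:
            return float(t)
        t_new = 0.5 * (low.mean() + high.mean())
        if t_new == t:
            return float(t)
        t = t_new
    return float(t)


def average_ranks(pooled: np.ndarray) -> np.ndarray:
    """Mid-ranks (ties averaged), computed by explicit counting."""
    pooled = np.asarray(pooled, dtype=np.float64)
    ranks = np.empty(pooled.size)
    for i, v in enumerate(pooled):
        less = np.sum(pooled < v)
        equal = np.sum(pooled == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def kruskal_wallis_brute(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction, from first principles."""
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = average_ranks(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += a.size * r.mean() ** 2
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if correction > 0:
        h /= correction
    p = float(chi2.sf(h, len(arrays) - 1))
    return float(h), p


def kruskal_wallis_permutation_p(groups, n_perm: int = 10_000, seed: int = 0) -> float:
    """Permutation p-value for the Kruskal-Wallis statistic."""
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    sizes = [a.size for a in arrays]
    pooled = np.concatenate(arrays)
    h_obs, _ = kruskal_wallis_brute(arrays)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        split = np.split(perm, np.cumsum(sizes)[:-1])
        h, _ = kruskal_wallis_brute(split)
        if h >= h_obs - 1e-12:
            count += 1
    return count / n_perm


def dunn_z_brute(groups) -> dict[tuple[int, int], float]:
    """Dunn pairwise z statistics recomputed from hand-counted ranks."""
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = average_ranks(pooled)
    means = []
    start = 0
    for a in arrays:
        means.append(ranks[start : start + a.size].mean())
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    base = n * (n + 1) / 12.0 - tie
    out = {}
    for i, j in itertools.combinations(range(len(arrays)), 2):
        denom2 = base * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        out[(i, j)] = 0.0 if denom2 <= 0 else (means[i] - means[j]) / np.sqrt(denom2)
    return out


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
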