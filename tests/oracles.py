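"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (grids, full enumeration) and shares
no code with the package's own computational paths.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import comb


def grid_posterior_means(y: np.ndarray, K: np.ndarray, grid: int = 51):
    """Posterior means of (psi, p11, p10) by brute-force grid integration.

    Uniform prior on the unit cube truncated to p10 < p11; likelihood is the
    occupancy mixture per bottle. Grid points at cell centers.
    """
    g = (np.arange(grid) + 0.5) / grid
    psi = g[:, None, None]
    p11 = g[None, :, None]
    p10 = g[None, None, :]
    ll = np.zeros((grid, grid, grid))
    for yi, Ki in zip(np.asarray(y, float), np.asarray(K, float)):
        b11 = p11**yi * (1 - p11) ** (Ki - yi)
        b10 = p10**yi * (1 - p10) ** (Ki - yi)
        ll = ll + np.log(psi * b11 + (1 - psi) * b10)
    mask = np.broadcast_to(p10 < p11, ll.shape)
    ll = np.where(mask, ll, -np.inf)
    w = np.exp(ll - ll.max())
    w /= w.sum()
    return (
        float((w.sum(axis=(1, 2)) * g).sum()),
        float((w.sum(axis=(0, 2)) * g).sum()),
        float((w.sum(axis=(0, 1)) * g).sum()),
    )


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p by enumerating all 2^n sign
    assignments (no ties/zeros assumed)."""
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mean_w = ranks.sum() / 2.0
    stat_obs = abs(w_obs - mean_w)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - mean_w) >= stat_obs - 1e-12:
            count += 1
    return count / 2.0**n


def exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by enumerating all group assignments
    (no ties assumed)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    na = len(a)
    w_obs = ranks[:na].sum()
    mean_w = na * (len(pooled) + 1) / 2.0
    stat_obs = abs(w_obs - mean_w)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= stat_obs - 1e-12:
            count += 1
    return count / total


def brute_force_two_cluster(values: np.ndarray):
    """Globally optimal 2-cluster partition by enumerating every nonempty
    bipartition; returns (labels in {'low','high'}, variance explained)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    best = None
    for bits in range(1, 2**n - 1):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        g1, g2 = v[mask], v[~mask]
        ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        if best is None or ssw < best[0] - 1e-12:
            best = (ssw, mask)
    ssw, mask = best
    hi = mask if v[mask].mean() > v[~mask].mean() else ~mask
    labels = np.where(hi, "high", "low")
    total = ((v - v.mean()) ** 2).sum()
    return labels, (1.0 - ssw / total) if total > 0 else 0.0
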