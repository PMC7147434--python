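"""Replicate quality control: discard PCR replicates dissimilar to their bottle.

For each bottle, technical replicates are embedded as eDNA-index vectors,
the bottle centroid is their arithmetic mean, and each replicate's
Bray-Curtis dissimilarity to that centroid is computed. The discard cutoff
is the pooled empirical (1 - alpha) quantile of centroid distances across
the whole dataset (one-sided upper 95% bound by default): pooling borrows
strength across bottles that individually hold only three replicates.
Bottles may drop to zero surviving replicates.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .community import edna_index
from .io_config import ReplicateCountTable

__all__ = [
    "replicate_distances",
    "flag_outlier_replicates",
    "apply_replicate_qc",
    "survivor_summary",
]


def _bc(x: np.ndarray, y: np.ndarray) -> float:
    denom = float((x + y).sum())
    if denom == 0:
        return np.nan
    return float(np.abs(x - y).sum() / denom)


def replicate_distances(table: ReplicateCountTable) -> pd.DataFrame:
    """Per-replicate Bray-Curtis dissimilarity to the bottle centroid.

    Bottles with a single replicate get distance 0 by convention. Replicates
    with zero total reads have undefined distance (NaN) and are treated as
    outliers downstream.
    """
    env = table.environmental()
    idx = edna_index(table, grouping="asv", samples=env.meta.index)
    meta = env.meta
    rows = []
    for bottle, grp in meta.groupby("bottle_id", sort=True):
        names = list(grp.index)
        if len(names) == 1:
            total = idx[names[0]].sum()
            rows.append((names[0], bottle, 0.0 if total > 0 else np.nan))
            continue
        vecs = idx[names].to_numpy(dtype=float).T
        centroid = vecs.mean(axis=0)
        for name, v in zip(names, vecs):
            d = np.nan if v.sum() == 0 else _bc(v, centroid)
            rows.append((name, bottle, d))
    out = pd.DataFrame(rows, columns=["sample_name", "bottle_id", "bray_curtis_to_centroid"])
    n_undef = int(out["bray_curtis_to_centroid"].isna().sum())
    if n_undef:
        warnings.warn(
            f"{n_undef} replicate(s) with zero reads have undefined centroid "
            "distance; flagged as outliers"
        )
    return out


def flag_outlier_replicates(
    distances: pd.DataFrame,
    alpha: float = 0.05,
    pooling: str = "pooled",
) -> pd.DataFrame:
    """Flag replicates whose centroid distance exceeds the pooled cutoff.

    The cutoff is the empirical (1 - alpha) quantile of all finite pooled
    distances; with fewer than 10 distances a normal approximation
    (mean + z_{1-alpha} * sd) is used instead, with a warning. Flags are
    strict (distance > cutoff), so ``alpha=0`` flags nothing.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    d = distances["bray_curtis_to_centroid"].to_numpy(dtype=float)
    finite = d[np.isfinite(d)]
    if len(finite) == 0:
        raise ValueError("no finite centroid distances to set a cutoff from")
    if pooling == "normal" or len(finite) < 10:
        if len(finite) < 10:
            warnings.warn(
                f"only {len(finite)} distances; using a normal approximation "
                "for the cutoff"
            )
        z = stats.norm.ppf(1.0 - alpha) if alpha > 0 else np.inf
        cutoff = float(finite.mean() + z * finite.std(ddof=1 if len(finite) > 1 else 0))
    else:
        cutoff = float(np.quantile(finite, 1.0 - alpha))
    out = distances.copy()
    out["cutoff"] = cutoff
    out["flagged"] = (d > cutoff) | ~np.isfinite(d)
    return out


def apply_replicate_qc(
    table: ReplicateCountTable,
    alpha: float = 0.05,
    pooling: str = "pooled",
) -> tuple[ReplicateCountTable, pd.DataFrame]:
    """One-shot QC: compute distances, flag, and drop flagged replicates.

    Centroids are not recomputed after discards (single pass). Returns the
    filtered table and the flag table.
    """
    distances = replicate_distances(table)
    flags = flag_outlier_replicates(distances, alpha=alpha, pooling=pooling)
    drop = flags.loc[flags["flagged"], "sample_name"]
    keep = table.meta.index.difference(drop)
    out = table.subset_samples(keep)
    out.provenance = table.provenance + ("qc-filtered",)
    return out, flags


def survivor_summary(flags: pd.DataFrame, meta: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-bottle survivor counts (how many bottles kept 3/2/1/0 replicates)."""
    per_bottle = flags.groupby("bottle_id")["flagged"].agg(
        n_replicates="size", n_flagged="sum"
    )
    per_bottle["n_surviving"] = per_bottle["n_replicates"] - per_bottle["n_flagged"]
    return per_bottle.reset_index()
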