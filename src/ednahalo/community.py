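"""Community-level analysis: eDNA index, Bray-Curtis, nMDS, PERMANOVA.

The eDNA abundance index is the Wisconsin double standardization: counts are
first turned into proportions within each technical replicate (removing
depth differences), then each taxon row is divided by its maximum across
replicates (removing amplification-efficiency differences), leaving values
in [0, 1] with every non-empty taxon peaking at exactly 1.

PERMANOVA partitions the variance of a (squared) Bray-Curtis distance matrix
among design factors via sequential (Type-I) sums of squares on the
Gower-centered inner-product matrix, with significance from free permutation
of rows; this mirrors the classic multi-factor adonis formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .io_config import ReplicateCountTable

__all__ = [
    "edna_index",
    "bray_curtis",
    "nmds",
    "NmdsResult",
    "permanova",
    "PermanovaResult",
]


def edna_index(
    table: ReplicateCountTable,
    grouping: str = "asv",
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """eDNA abundance index matrix (taxa x replicates), values in [0, 1].

    ``grouping`` is ``asv``, ``phylum`` or ``taxon_unit``; for aggregated
    groupings counts are summed within the group *before* proportions are
    taken. Environmental replicates only. All-zero taxa stay at 0 with a
    warning; zero-total replicates stay at 0.
    """
    env = table.environmental()
    wide = env.wide()
    if samples is not None:
        wide = wide.reindex(columns=pd.Index(samples), fill_value=0.0)
    if grouping != "asv":
        if table.taxonomy is None:
            raise ValueError(f"grouping={grouping!r} requires a taxonomy table")
        if grouping not in table.taxonomy.columns:
            raise ValueError(f"unknown grouping {grouping!r}")
        labels = table.taxonomy[grouping].reindex(wide.index)
        wide = wide.groupby(labels, sort=True).sum()
    totals = wide.sum(axis=0)
    zero_cols = totals[totals == 0].index
    if len(zero_cols):
        warnings.warn(f"{len(zero_cols)} replicate(s) have zero total reads")
    props = wide.divide(totals.replace(0.0, np.nan), axis=1).fillna(0.0)
    row_max = props.max(axis=1)
    zero_rows = row_max[row_max == 0].index
    if len(zero_rows):
        warnings.warn(f"{len(zero_rows)} taxa have no reads anywhere; left at 0")
    index = props.divide(row_max.replace(0.0, np.nan), axis=0).fillna(0.0)
    return index


def bray_curtis(matrix: pd.DataFrame, axis: str = "columns") -> pd.DataFrame:
    """Square symmetric Bray-Curtis dissimilarity matrix.

    ``axis='columns'`` compares column vectors (replicates of a taxa x
    replicate matrix). BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); pairs of
    all-zero vectors get distance 0 with a warning.
    """
    X = matrix.to_numpy(dtype=float)
    ids = matrix.columns if axis == "columns" else matrix.index
    if axis == "columns":
        X = X.T
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    zero = X.sum(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero vector(s); involved pairs of two "
            "empty vectors get distance 0, mixed pairs distance 1"
        )
        zz = np.outer(zero, zero)
        D[zz] = 0.0
        mixed = np.logical_xor.outer(zero, zero)
        D[mixed] = 1.0
        np.fill_diagonal(D, 0.0)
    D = np.nan_to_num(D, nan=0.0)
    return pd.DataFrame(D, index=ids, columns=ids)


@dataclass
class NmdsResult:
    coords: pd.DataFrame  # points x dims
    stress: float  # Kruskal stress-1
    n_starts: int
    converged: bool


def nmds(
    dist: pd.DataFrame,
    dims: int = 2,
    max_starts: int = 1000,
    seed: int = 0,
    procrustes_tol: float = 1e-6,
) -> NmdsResult:
    """Non-metric MDS by SMACOF with monotone regression, best of random starts.

    Runs up to ``max_starts`` random initializations, keeping the lowest
    Kruskal stress-1 configuration; declares convergence as soon as a new
    start reproduces the incumbent best configuration within Procrustes RMSE
    ``procrustes_tol`` (or the stress reaches ~0).
    """
    n = dist.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} points for {dims}-D nMDS")
    D = dist.to_numpy(dtype=float)
    if np.allclose(D[~np.eye(n, dtype=bool)], D[0, 1]):
        warnings.warn("all pairwise distances equal; configuration is arbitrary")
    rng = np.random.default_rng(seed)
    best_coords, best_stress = None, np.inf
    converged = False
    starts = 0
    from scipy.spatial import procrustes as _procrustes

    for starts in range(1, max_starts + 1):
        model = MDS(
            n_components=dims,
            metric="precomputed",
            metric_mds=False,
            init="random",
            n_init=1,
            max_iter=300,
            random_state=int(rng.integers(2**31 - 1)),
            normalized_stress=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            coords = model.fit_transform(D)
        stress = float(model.stress_)
        if best_coords is not None:
            try:
                _, _, disparity = _procrustes(best_coords, coords)
                rmse = np.sqrt(disparity / n)
            except ValueError:  # degenerate (all-identical) configuration
                rmse = np.inf
            if stress < best_stress:
                best_coords, best_stress = coords, stress
            if rmse < procrustes_tol or best_stress < 1e-9:
                converged = True
                break
        else:
            best_coords, best_stress = coords, stress
            if best_stress < 1e-9 and max_starts == 1:
                converged = True
    coords_df = pd.DataFrame(
        best_coords, index=dist.index, columns=[f"nmds{i+1}" for i in range(dims)]
    )
    return NmdsResult(
        coords=coords_df, stress=best_stress, n_starts=starts, converged=converged
    )


@dataclass
class PermanovaResult:
    """Sequential variance partition of a distance matrix."""

    table: pd.DataFrame  # term, df, sum_sq, r2, f, p (residual/total rows included)
    n_permutations: int

    def r2(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "r2"])

    def p(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of X and its rank."""
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    return Q @ Q.T, int(keep.sum())


def permanova(
    dist: pd.DataFrame,
    factors: pd.DataFrame,
    terms: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Multi-factor PERMANOVA with sequential (Type-I) sums of squares.

    ``factors`` rows must align with the distance matrix; categorical
    columns are dummy-coded, numeric ones enter as given. p-values come from
    free permutation of the distance matrix rows:
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = dist.index
    if not factors.index.equals(ids):
        factors = factors.loc[ids]
    n = len(ids)
    D2 = dist.to_numpy(dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    total_ss = float(np.trace(G))
    if total_ss <= 1e-12:
        raise ValueError("distance matrix has no variance to partition")

    # cumulative design matrices: intercept, then one term at a time
    blocks = [np.ones((n, 1))]
    dfs, hats = [], []
    prev_rank = 1
    prev_hat, _ = _hat(np.ones((n, 1)))
    degenerate = []
    for term in terms:
        col = factors[term]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 7:
            X_t = col.to_numpy(dtype=float)[:, None]
        else:
            X_t = pd.get_dummies(col.astype(str), drop_first=True).to_numpy(float)
        if X_t.shape[1] == 0:
            degenerate.append(term)
        blocks.append(X_t)
        H, rank = _hat(np.hstack(blocks))
        dfs.append(rank - prev_rank)
        hats.append(H)
        prev_rank = rank
    if degenerate:
        warnings.warn(
            f"terms with a single level contribute no variance: {degenerate}"
        )
    full_hat = hats[-1]
    df_resid = n - prev_rank

    def term_stats(Gmat: np.ndarray):
        ss, prev = [], float(np.sum(prev_hat_init * Gmat))
        for H in hats:
            cur = float(np.sum(H * Gmat))
            ss.append(cur - prev)
            prev = cur
        ss_resid = float(np.trace(Gmat)) - float(np.sum(full_hat * Gmat))
        f = [
            (s / d) / (ss_resid / df_resid) if d > 0 and ss_resid > 0 else np.nan
            for s, d in zip(ss, dfs)
        ]
        return np.array(ss), ss_resid, np.array(f)

    prev_hat_init = prev_hat
    ss_obs, ss_resid, f_obs = term_stats(G)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        _, _, f_p = term_stats(Gp)
        exceed += np.where(np.isnan(f_obs), 0, f_p >= f_obs)
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    rows = []
    for i, term in enumerate(terms):
        if dfs[i] == 0:
            rows.append((term, 0, 0.0, 0.0, np.nan, 1.0))
        else:
            rows.append(
                (term, dfs[i], ss_obs[i], ss_obs[i] / total_ss, f_obs[i], pvals[i])
            )
    rows.append(("residual", df_resid, ss_resid, ss_resid / total_ss, np.nan, np.nan))
    rows.append(("total", n - 1, total_ss, 1.0, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["term", "df", "sum_sq", "r2", "f", "p"])
    return PermanovaResult(table=out, n_permutations=n_perm)
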