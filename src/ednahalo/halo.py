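"""Spatial halo detection along eelgrass transects.

The procedure mirrors how episodic dinoflagellate blooms are isolated and
their spatial footprint tested:

1. :func:`transect_events` — per (taxon unit, site-month), the grand mean of
   the taxon's eDNA indices over the transect's technical replicates;
2. :func:`split_high_low` — exact two-cluster 1-D partition of event means
   (globally optimal k-means via the contiguity of optimal 1-D clusters in
   sorted order — deterministic, no random restarts);
3. :func:`gmm_two_group` — pooled per-position index values from the
   high-abundance transects fit with a two-component univariate Gaussian
   mixture (equal- and unequal-variance models compared by BIC); each
   transect position joins the component holding the majority of its
   values' posterior memberships;
4. :func:`rank_sum_test` — two-sided Wilcoxon rank-sum between the two
   position groups' values;
5. :func:`adjacent_dissimilarity_check` — Bray-Curtis dissimilarity between
   adjacent alongshore positions, grouped by spacing in meters, under a
   Kruskal-Wallis test: a spatial-autocorrelation control showing that
   community turnover does not itself scale with distance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .io_config import POSITION_ORDER
from .community import bray_curtis

__all__ = [
    "transect_events",
    "split_high_low",
    "gmm_two_group",
    "HaloResult",
    "rank_sum_test",
    "adjacent_dissimilarity_check",
]


def transect_events(
    index: pd.DataFrame,
    meta: pd.DataFrame,
    taxa: Sequence[str],
) -> pd.DataFrame:
    """Grand mean eDNA index per (taxon unit, site-month) transect.

    ``index`` is a taxon_unit-grouped index matrix (taxa x replicates).
    Events are emitted only where the taxon occurs on the transect
    (mean > 0); a taxon absent everywhere draws a warning.
    """
    meta = meta.loc[meta.index.intersection(index.columns)]
    rows = []
    for taxon in taxa:
        if taxon not in index.index or index.loc[taxon].sum() == 0:
            warnings.warn(f"taxon {taxon!r} absent from the index; no events")
            continue
        for (site, month), grp in meta.groupby(["site", "month"], sort=True,
                                               observed=True):
            vals = index.loc[taxon, list(grp.index)]
            mean = float(vals.mean())
            if mean > 0:
                rows.append((taxon, site, month, mean))
    return pd.DataFrame(rows, columns=["taxon_unit", "site", "month", "mean_index"])


def split_high_low(events: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Exact optimal two-cluster split of event means, plus variance explained.

    For k = 2 in one dimension, the optimal (within-cluster sum of squares)
    partition is contiguous in sorted order, so scanning the n - 1 cut
    points is exhaustive. The cluster with the larger center is labelled
    ``high``. Returns the events with an ``abundance_class`` column and
    between-cluster SS / total SS.
    """
    vals = events["mean_index"].to_numpy(dtype=float)
    if len(vals) < 2 or np.unique(vals).size < 2:
        raise ValueError("need >= 2 events with distinct values to split")
    order = np.argsort(vals)
    sv = vals[order]
    best_cut, best_ssw = None, np.inf
    for cut in range(1, len(sv)):
        left, right = sv[:cut], sv[cut:]
        ssw = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if ssw < best_ssw:
            best_ssw, best_cut = ssw, cut
    labels = np.empty(len(sv), dtype=object)
    labels[order[:best_cut]] = "low"
    labels[order[best_cut:]] = "high"
    out = events.copy()
    out["abundance_class"] = labels
    total_ss = float(((vals - vals.mean()) ** 2).sum())
    variance_explained = 1.0 - best_ssw / total_ss if total_ss > 0 else 0.0
    return out, float(variance_explained)


@dataclass
class HaloResult:
    """Two-group classification of transect positions."""

    position_cluster: pd.Series  # position -> 'A' | 'B'
    values_by_position: dict  # position -> np.ndarray of index values
    component_means: tuple[float, float]
    covariance_type: str  # GMM variance structure chosen by BIC
    bic: float
    rank_sum_p: float
    variance_explained: float  # between-cluster SS / total SS of the values
    degenerate: bool = False


def gmm_two_group(
    values_by_position: Mapping[str, np.ndarray],
    seed: int = 0,
) -> HaloResult:
    """Cluster transect positions into two groups via a 1-D Gaussian mixture.

    Values (pooled across high-abundance transects) are fit with
    two-component mixtures under equal (``tied``) and unequal (``full``)
    variance; the lower-BIC model wins. Each position is assigned to the
    component holding the majority (mean posterior membership) of its
    values. Group ``A`` is the component containing the eelgrass position
    (or, failing that, the lower-mean component); ``B`` is the other. The
    rank-sum test compares pooled values between the two position groups.
    """
    positions = [p for p in POSITION_ORDER if p in values_by_position]
    positions += [p for p in values_by_position if p not in positions]
    if len(positions) < 2:
        raise ValueError("need values for at least 2 positions")
    arrays = {p: np.asarray(values_by_position[p], dtype=float) for p in positions}
    pooled = np.concatenate([arrays[p] for p in positions])
    if len(pooled) < 4:
        raise ValueError("need at least 4 values to fit a two-component mixture")

    if np.ptp(pooled) == 0:
        warnings.warn("all values identical; single effective component")
        cluster = pd.Series("A", index=pd.Index(positions, name="position"))
        return HaloResult(
            position_cluster=cluster,
            values_by_position=arrays,
            component_means=(float(pooled[0]), float(pooled[0])),
            covariance_type="degenerate",
            bic=np.nan,
            rank_sum_p=1.0,
            variance_explained=0.0,
            degenerate=True,
        )

    X = pooled[:, None]
    best = None
    for cov in ("tied", "full"):
        gm = GaussianMixture(
            n_components=2,
            covariance_type=cov,
            n_init=10,
            init_params="k-means++",
            random_state=seed,
            max_iter=500,
        ).fit(X)
        bic = gm.bic(X)
        if best is None or bic < best[1]:
            best = (gm, bic, cov)
    gm, bic, cov = best

    resp = gm.predict_proba(X)
    comp_of_pos = {}
    start = 0
    for p in positions:
        k = len(arrays[p])
        comp_of_pos[p] = int(resp[start : start + k].mean(axis=0).argmax())
        start += k
    means = gm.means_.ravel()

    if "Eg" in comp_of_pos:
        a_comp = comp_of_pos["Eg"]
    else:
        a_comp = int(means.argmin())
    cluster = pd.Series(
        {p: ("A" if c == a_comp else "B") for p, c in comp_of_pos.items()},
        name="cluster",
    ).rename_axis("position")
    cluster = cluster.loc[positions]

    group_a = np.concatenate(
        [arrays[p] for p in positions if cluster[p] == "A"]
    ) if (cluster == "A").any() else np.array([])
    group_b = np.concatenate(
        [arrays[p] for p in positions if cluster[p] == "B"]
    ) if (cluster == "B").any() else np.array([])
    if len(group_a) and len(group_b):
        p_rs = rank_sum_test(group_a, group_b)
        grand = pooled.mean()
        ss_between = len(group_a) * (group_a.mean() - grand) ** 2 + len(group_b) * (
            group_b.mean() - grand
        ) ** 2
        ss_total = ((pooled - grand) ** 2).sum()
        ve = float(ss_between / ss_total) if ss_total > 0 else 0.0
    else:
        warnings.warn("mixture assigned every position to one component")
        p_rs, ve = 1.0, 0.0
    return HaloResult(
        position_cluster=cluster,
        values_by_position=arrays,
        component_means=(float(means[a_comp]), float(means[1 - a_comp])),
        covariance_type=cov,
        bic=float(bic),
        rank_sum_p=p_rs,
        variance_explained=ve,
    )


def rank_sum_test(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two value groups.

    Exact null when the smaller group has <= 10 values and there are no
    ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (min(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    if has_ties and np.ptp(combined) == 0:
        return 1.0
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


_ALONGSHORE = ("1", "3", "6", "10", "15")


def adjacent_dissimilarity_check(
    index: pd.DataFrame,
    meta: pd.DataFrame,
) -> tuple[pd.DataFrame, float, float]:
    """Spatial-autocorrelation control across alongshore spacings.

    Per site-month transect, each position's replicates are averaged into
    one index vector (all ASVs); Bray-Curtis dissimilarity between adjacent
    alongshore positions is grouped by their spacing in meters (Eg and Ba
    are excluded — their metric distance to the transect varies by site)
    and a Kruskal-Wallis rank test asks whether dissimilarity depends on
    spacing. Returns (pairs table, H, p).
    """
    meta = meta.loc[meta.index.intersection(index.columns)]
    rows = []
    for (site, month), grp in meta.groupby(["site", "month"], sort=True,
                                           observed=True):
        pos_present = [
            p for p in _ALONGSHORE if (grp["position"] == p).any()
        ]
        if len(pos_present) < 3:
            continue
        vectors = {}
        for p in pos_present:
            names = list(grp.index[grp["position"] == p])
            vectors[p] = index[names].mean(axis=1)
        mat = pd.DataFrame(vectors)
        D = bray_curtis(mat, axis="columns")
        for p1, p2 in itertools.pairwise(pos_present):
            spacing = int(p2) - int(p1)
            rows.append((site, month, p1, p2, spacing, float(D.loc[p1, p2])))
    pairs = pd.DataFrame(
        rows,
        columns=["site", "month", "from_pos", "to_pos", "spacing_m", "bray_curtis"],
    )
    if pairs.empty or pairs["spacing_m"].nunique() < 2:
        raise ValueError(
            "need adjacent-position pairs in at least 2 spacing groups"
        )
    groups = [g["bray_curtis"].to_numpy() for _, g in pairs.groupby("spacing_m")]
    if np.ptp(pairs["bray_curtis"].to_numpy()) == 0:
        return pairs, 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return pairs, float(H), float(p)
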