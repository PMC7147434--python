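"""Phylum-level habitat association between transect extremes.

For each phylum and site-month with samples at both transect extremes, the
relative abundance measure is

    mean eDNA index over Eg replicates - mean eDNA index over Ba replicates

so positive values mean higher abundance inside the eelgrass bed and
negative values higher abundance over bare substrate. Per phylum, the
site-month measures feed a two-sided paired Wilcoxon signed-rank test
(exact null enumeration for small n without ties, tie-corrected normal
approximation otherwise) with Bonferroni correction across the phyla
actually tested.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_abundance",
    "paired_wilcoxon",
    "paired_wilcoxon_bonferroni",
]

_EXACT_N = 12


def relative_abundance(
    index: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Eg-minus-Ba mean eDNA index per (phylum, site, month).

    ``index`` is a phylum-grouped eDNA index matrix (phyla x replicates);
    ``meta`` supplies site, month and position per replicate. Site-months
    missing either extreme are skipped with a log entry.
    """
    meta = meta.loc[meta.index.intersection(index.columns)]
    rows = []
    skipped = []
    for (site, month), grp in meta.groupby(["site", "month"], sort=True,
                                           observed=True):
        eg = grp.index[grp["position"] == "Eg"]
        ba = grp.index[grp["position"] == "Ba"]
        if len(eg) == 0 or len(ba) == 0:
            skipped.append((site, month))
            continue
        eg_mean = index[list(eg)].mean(axis=1)
        ba_mean = index[list(ba)].mean(axis=1)
        for phylum in index.index:
            rows.append(
                (
                    phylum,
                    site,
                    month,
                    float(eg_mean[phylum]),
                    float(ba_mean[phylum]),
                    float(eg_mean[phylum] - ba_mean[phylum]),
                )
            )
    if skipped:
        warnings.warn(
            f"site-months missing an Eg or Ba sample were skipped: {skipped}"
        )
    return pd.DataFrame(
        rows, columns=["phylum", "site", "month", "eg_mean", "ba_mean", "value"]
    )


def paired_wilcoxon(differences: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Exact enumeration of sign assignments for n <= 12 without ties or zero
    differences; tie-corrected normal approximation otherwise. All-zero
    differences give p = 1. Fewer than 2 pairs is an error.
    """
    d = np.asarray(differences, dtype=float)
    if len(d) < 2:
        raise ValueError("paired Wilcoxon needs at least 2 pairs")
    if np.all(d == 0):
        return 1.0
    nz = d[d != 0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz) or (d == 0).any()
    method = "exact" if (len(nz) <= _EXACT_N and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         zero_method="wilcox")
    return float(res.pvalue)


def paired_wilcoxon_bonferroni(
    measures: pd.DataFrame, m: Optional[int] = None
) -> pd.DataFrame:
    """Per-phylum habitat-association table with Bonferroni-adjusted p-values.

    ``measures`` as from :func:`relative_abundance`. Phyla with fewer than 2
    site-month pairs are dropped with a warning. ``m`` defaults to the
    number of phyla actually tested; adjusted p = min(1, m * p).
    """
    groups = {p: g["value"].to_numpy() for p, g in measures.groupby("phylum", sort=True)}
    testable = {p: v for p, v in groups.items() if len(v) >= 2}
    dropped = sorted(set(groups) - set(testable))
    if dropped:
        warnings.warn(f"phyla with < 2 site-month pairs not tested: {dropped}")
    if not testable:
        raise ValueError("no phylum has the >= 2 site-month pairs needed to test")
    if m is None:
        m = len(testable)
    rows = []
    for phylum, vals in testable.items():
        p_raw = paired_wilcoxon(vals)
        rows.append(
            (
                phylum,
                len(vals),
                float(np.mean(vals)),
                p_raw,
                min(1.0, m * p_raw),
            )
        )
    return pd.DataFrame(
        rows, columns=["phylum", "n_pairs", "mean_measure", "p_raw", "p_adjusted"]
    )
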