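"""Positive-control decontamination and low-read replicate removal.

Cross-sample contamination (index hopping, tag jumping) shows up as
environmental ASVs appearing in positive-control tissue samples. The fix:
compute each ASV's maximum proportional representation across all
positive-control replicates, subtract that proportion from the same ASV in
every field replicate (floored at zero), and map the adjusted proportions
back to the replicate's original read depth. Counts may be fractional
afterwards; the abundance index downstream renormalizes anyway, so the
subtracted mass is not redistributed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_config import ReplicateCountTable

__all__ = [
    "ControlProfile",
    "max_control_proportion",
    "subtract_contamination",
    "drop_low_read_replicates",
]


@dataclass
class ControlProfile:
    """Per-ASV maximum proportion observed in positive-control replicates.

    ASVs never seen in controls have value 0. ``lookup`` returns 0 for ASVs
    absent from the profile.
    """

    proportions: pd.Series  # asv_id -> max proportion in [0, 1]
    n_controls: int

    def lookup(self, asv_ids: Sequence[str]) -> np.ndarray:
        return self.proportions.reindex(asv_ids, fill_value=0.0).to_numpy()

    @classmethod
    def zero(cls) -> "ControlProfile":
        return cls(pd.Series(dtype=float), n_controls=0)


def max_control_proportion(table: ReplicateCountTable) -> ControlProfile:
    """Build a :class:`ControlProfile` from the table's positive controls.

    Control replicates with zero total reads are excluded from the maximum;
    if no positive control carries reads, raises — pass
    ``profile=ControlProfile.zero()`` to :func:`subtract_contamination`
    to skip the stage explicitly.
    """
    pos = table.samples_of_class("positive_control")
    if len(pos) == 0:
        raise ValueError(
            "table has no positive-control replicates; to skip decontamination "
            "use ControlProfile.zero() explicitly"
        )
    sub = table.counts[table.counts["sample_name"].isin(pos)]
    totals = sub.groupby("sample_name")["count"].sum()
    live = totals.index[totals > 0]
    if len(live) == 0:
        raise ValueError(
            "all positive-control replicates have zero reads; cannot build a "
            "contamination profile (skip the stage explicitly if intended)"
        )
    sub = sub[sub["sample_name"].isin(live)].copy()
    sub["prop"] = sub["count"] / sub["sample_name"].map(totals)
    prof = sub.groupby("asv_id")["prop"].max()
    return ControlProfile(proportions=prof, n_controls=int(len(live)))


def subtract_contamination(
    table: ReplicateCountTable,
    profile: ControlProfile,
    control_taxa: Sequence[str] = (),
) -> ReplicateCountTable:
    """Subtract the control profile from environmental replicates.

    Per environmental replicate: each ASV's within-replicate proportion is
    reduced by its profile value, floored at 0, and rescaled back to the
    replicate's original total read count. ASVs assigned to control tissue
    (``taxon_unit`` in ``control_taxa``) are removed outright from
    environmental samples. Control samples pass through unchanged.
    """
    env = table.samples_of_class("environmental")
    counts = table.counts
    is_env = counts["sample_name"].isin(env)
    env_counts = counts[is_env].copy()
    other = counts[~is_env]

    totals = env_counts.groupby("sample_name")["count"].sum()
    env_counts["total"] = env_counts["sample_name"].map(totals)
    prop = env_counts["count"] / env_counts["total"]
    adj = np.maximum(prop - profile.lookup(env_counts["asv_id"]), 0.0)
    env_counts["count"] = adj * env_counts["total"]
    env_counts = env_counts.drop(columns="total")

    if control_taxa and table.taxonomy is not None:
        ctrl_asvs = table.taxonomy.index[
            table.taxonomy["taxon_unit"].isin(control_taxa)
        ]
        env_counts = env_counts[~env_counts["asv_id"].isin(ctrl_asvs)]

    out = pd.concat([env_counts, other], ignore_index=True)
    return table.with_counts(out, add_provenance="decontaminated",
                             keep_all_samples=True)


def drop_low_read_replicates(
    table: ReplicateCountTable, min_reads: float
) -> tuple[ReplicateCountTable, pd.DataFrame]:
    """Drop environmental replicates whose total reads fall below ``min_reads``.

    Returns the filtered table and a log of removed replicates with totals.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = table.replicate_totals()
    env = table.samples_of_class("environmental")
    low = totals.loc[env][totals.loc[env] < min_reads]
    removed = pd.DataFrame(
        {"sample_name": low.index, "total_reads": low.to_numpy()}
    )
    keep = table.meta.index.difference(low.index)
    if len(keep.intersection(env)) == 0 and len(env) > 0:
        warnings.warn(
            f"all {len(env)} environmental replicates fall below "
            f"min_reads={min_reads}; result is empty"
        )
    out = table.subset_samples(keep)
    out.provenance = table.provenance + ("low-read-filtered",)
    return out, removed
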