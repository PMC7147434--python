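"""End-to-end pipeline: simulate/load -> decontaminate -> occupancy-filter ->
replicate QC -> eDNA index -> ordination, variance partition, habitat and
halo analyses, with one config, one master seed and one JSON run manifest.

Per-stage seeds are derived deterministically from the master seed with
:class:`numpy.random.SeedSequence` spawning, so skipping a stage never
shifts the randomness of the stages after it. With a fixed master seed the
entire output directory is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .community import bray_curtis, edna_index, nmds, permanova
from .decontam import (
    ControlProfile,
    drop_low_read_replicates,
    max_control_proportion,
    subtract_contamination,
)
from .habitat import paired_wilcoxon_bonferroni, relative_abundance
from .halo import (
    adjacent_dissimilarity_check,
    gmm_two_group,
    split_high_low,
    transect_events,
)
from .io_config import Config, ReplicateCountTable, write_count_table
from .occupancy import (
    asv_presence_probabilities,
    build_detection_histories,
    cull_asvs,
    fit_occupancy_models,
)
from .replicate_qc import apply_replicate_qc, survivor_summary
from .synthetic import SimulationParams, puget_sound_design, simulate_study

__all__ = ["RunManifest", "PipelineError", "run_all"]

_STAGES = (
    "simulate",
    "decontam",
    "occupancy",
    "qc",
    "index",
    "ordinate",
    "permanova",
    "habitat",
    "halo",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    """Config snapshot, per-stage seeds and attrition accounting."""

    config: dict
    seeds: dict
    stages: list = field(default_factory=list)
    version: str = __version__
    timestamp: Optional[str] = None

    def record(self, stage: str, status: str, table: Optional[ReplicateCountTable] = None, **extra):
        entry = {"stage": stage, "status": status}
        if table is not None:
            entry["n_asvs"] = table.n_asvs()
            entry["total_reads"] = round(table.total_reads(), 3)
            entry["n_replicates"] = int(len(table.meta))
        entry.update(extra)
        self.stages.append(entry)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stage_seeds(master: int) -> dict:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % 2**31)
        for stage, child in zip(_STAGES, children)
    }


def run_all(
    config: Config,
    outdir: str | Path,
    table: Optional[ReplicateCountTable] = None,
    sim_params: Optional[SimulationParams] = None,
) -> RunManifest:
    """Run every stage in order, writing TSV outputs and a manifest.

    Pass an input ``table`` to analyse real data, or leave it ``None`` to
    simulate one (``sim_params`` overrides the default study design; its
    seed is replaced by the derived stage seed). Stages named in
    ``config.skip_stages`` are skipped and downstream stages run on the
    unfiltered table.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seeds=seeds,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S") if config.record_timestamps else None,
    )
    skip = set(config.skip_stages)

    def skippable(stage: str) -> bool:
        if stage in skip:
            manifest.record(stage, "skipped")
            return True
        return False

    try:
        # -- simulate / load ------------------------------------------------
        if table is None:
            params = sim_params or puget_sound_design()
            params = dataclasses.replace(params, seed=seeds["simulate"])
            table, truth = simulate_study(params)
            write_count_table(table, outdir / "counts_raw.tsv")
            table.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t")
            truth.z.to_csv(outdir / "truth_occupancy.tsv", sep="\t")
            truth.bloom_events.to_csv(outdir / "truth_blooms.tsv", sep="\t", index=False)
            manifest.record("simulate", "ok", table,
                            n_bottles=int(truth.z.shape[0]))
        else:
            manifest.record("simulate", "skipped (input table provided)", table)

        # -- decontamination ------------------------------------------------
        if not skippable("decontam"):
            try:
                profile = max_control_proportion(table)
            except ValueError as err:
                warnings.warn(f"decontamination profile unavailable: {err}")
                profile = ControlProfile.zero()
            table = subtract_contamination(table, profile,
                                           control_taxa=config.control_taxa)
            table, removed = drop_low_read_replicates(table, config.min_reads)
            removed.to_csv(outdir / "removed_low_read.tsv", sep="\t", index=False)
            write_count_table(table, outdir / "counts_decontaminated.tsv")
            manifest.record("decontam", "ok", table,
                            n_low_read_removed=int(len(removed)))

        # -- occupancy filtering --------------------------------------------
        if not skippable("occupancy"):
            hist = build_detection_histories(table.environmental(),
                                             config.detect_threshold)
            fit = fit_occupancy_models(
                hist,
                draws=config.mcmc_draws,
                burn_in=config.mcmc_burn_in,
                chains=config.mcmc_chains,
                seed=seeds["occupancy"],
            )
            presence = asv_presence_probabilities(
                fit, hist, aggregation=config.occupancy_aggregation
            )
            summary = fit.summary.join(presence)
            summary.to_csv(outdir / "occupancy_summary.tsv", sep="\t",
                           float_format="%.6g")
            keep = ~fit.summary["converged"]
            table, log = cull_asvs(table, presence,
                                   threshold=config.occupancy_threshold,
                                   keep=keep)
            write_count_table(table, outdir / "counts_occupancy.tsv")
            manifest.record("occupancy", "ok", table, **log)

        # -- replicate QC ---------------------------------------------------
        if not skippable("qc"):
            table, flags = apply_replicate_qc(table, alpha=config.qc_alpha,
                                              pooling=config.qc_pooling)
            flags.to_csv(outdir / "qc_flags.tsv", sep="\t", index=False,
                         float_format="%.6g")
            survivor_summary(flags).to_csv(outdir / "qc_survivors.tsv",
                                           sep="\t", index=False)
            write_count_table(table, outdir / "counts_qc.tsv")
            manifest.record("qc", "ok", table,
                            n_flagged=int(flags["flagged"].sum()))

        env_meta = table.environmental().meta

        # -- eDNA indices ---------------------------------------------------
        idx_asv = edna_index(table, grouping="asv")
        idx_asv.to_csv(outdir / "index_asv.tsv", sep="\t", float_format="%.6g")
        idx_phylum = idx_unit = None
        if table.taxonomy is not None:
            idx_phylum = edna_index(table, grouping="phylum")
            idx_phylum.to_csv(outdir / "index_phylum.tsv", sep="\t",
                              float_format="%.6g")
            idx_unit = edna_index(table, grouping="taxon_unit")
        manifest.record("index", "ok", table)

        # -- ordination (per site-month, as many small nMDS fits) -----------
        if not skippable("ordinate"):
            coords_all, stresses = [], []
            for (site, month), grp in env_meta.groupby(["site", "month"],
                                                       sort=True, observed=True):
                names = [n for n in grp.index if n in idx_asv.columns]
                if len(names) < config.nmds_dims + 1:
                    continue
                D = bray_curtis(idx_asv[names], axis="columns")
                res = nmds(D, dims=config.nmds_dims,
                           max_starts=config.nmds_max_starts,
                           seed=seeds["ordinate"])
                c = res.coords.copy()
                c.insert(0, "site", site)
                c.insert(1, "month", month)
                coords_all.append(c)
                stresses.append((site, month, res.stress, res.n_starts,
                                 res.converged))
            if coords_all:
                pd.concat(coords_all).rename_axis("sample_name").to_csv(
                    outdir / "nmds_coords.tsv", sep="\t", float_format="%.6g")
                pd.DataFrame(
                    stresses,
                    columns=["site", "month", "stress", "n_starts", "converged"],
                ).to_csv(outdir / "nmds_stress.tsv", sep="\t", index=False,
                         float_format="%.6g")
            manifest.record("ordinate", "ok", n_ordinations=len(stresses))

        # -- PERMANOVA ------------------------------------------------------
        if not skippable("permanova"):
            names = [n for n in env_meta.index if n in idx_asv.columns]
            D = bray_curtis(idx_asv[names], axis="columns")
            factors = env_meta.loc[names, ["site", "month", "position",
                                           "distance_m"]].copy()
            terms = list(config.permanova_terms)
            if config.permanova_distance_as == "continuous" and "position" in terms:
                factors["position"] = factors["distance_m"]
                factors = factors.dropna(subset=["position"])
                D = D.loc[factors.index, factors.index]
            res = permanova(D, factors, terms, n_perm=config.n_permutations,
                            seed=seeds["permanova"])
            res.table.to_csv(outdir / "permanova.tsv", sep="\t", index=False,
                             float_format="%.6g")
            manifest.record(
                "permanova", "ok",
                r2={t: round(res.r2(t), 4) for t in terms},
            )

        # -- phylum habitat associations ------------------------------------
        if not skippable("habitat") and idx_phylum is not None:
            measures = relative_abundance(idx_phylum, env_meta)
            measures.to_csv(outdir / "habitat_measures.tsv", sep="\t",
                            index=False, float_format="%.6g")
            assoc = paired_wilcoxon_bonferroni(measures)
            assoc.to_csv(outdir / "habitat_associations.tsv", sep="\t",
                         index=False, float_format="%.6g")
            manifest.record("habitat", "ok",
                            n_phyla_tested=int(len(assoc)),
                            n_significant=int((assoc["p_adjusted"] < 0.05).sum()))

        # -- halo detection --------------------------------------------------
        if not skippable("halo") and idx_unit is not None:
            tax = table.taxonomy
            halo_units = sorted(
                set(tax.loc[tax["phylum"] == config.halo_taxa_phylum,
                            "taxon_unit"].dropna())
                & set(idx_unit.index)
            )
            events = transect_events(idx_unit, env_meta, halo_units)
            if len(events) >= 2 and events["mean_index"].nunique() >= 2:
                events, ve_split = split_high_low(events)
                events.to_csv(outdir / "halo_events.tsv", sep="\t", index=False,
                              float_format="%.6g")
                high = events[events["abundance_class"] == "high"]
                values = _position_values(idx_unit, env_meta, high)
                result = gmm_two_group(values, seed=seeds["halo"])
                result.position_cluster.to_csv(outdir / "halo_clusters.tsv",
                                               sep="\t")
                pairs, H, kw_p = adjacent_dissimilarity_check(idx_asv, env_meta)
                pairs.to_csv(outdir / "halo_spacing_pairs.tsv", sep="\t",
                             index=False, float_format="%.6g")
                summary = pd.DataFrame(
                    [
                        ("n_events", len(events)),
                        ("n_high_events", len(high)),
                        ("split_variance_explained", round(ve_split, 6)),
                        ("gmm_covariance", result.covariance_type),
                        ("gmm_variance_explained",
                         round(result.variance_explained, 6)),
                        ("rank_sum_p", result.rank_sum_p),
                        ("kruskal_H", round(H, 6)),
                        ("kruskal_p", kw_p),
                    ],
                    columns=["quantity", "value"],
                )
                summary.to_csv(outdir / "halo_tests.tsv", sep="\t", index=False)
                manifest.record("halo", "ok", n_high_events=int(len(high)),
                                rank_sum_p=result.rank_sum_p,
                                cluster={p: c for p, c in
                                         result.position_cluster.items()})
            else:
                manifest.record("halo", "skipped (too few events)")
    except Exception as err:
        manifest.record("error", f"{type(err).__name__}: {err}")
        manifest.write(outdir / "manifest.json")
        raise PipelineError(str(err)) from err

    manifest.write(outdir / "manifest.json")
    return manifest


def _position_values(
    idx_unit: pd.DataFrame, meta: pd.DataFrame, high_events: pd.DataFrame
) -> dict:
    """Per-position mean index values of each high-abundance (taxon,
    site-month) event."""
    values: dict[str, list[float]] = {}
    for taxon, site, month in zip(
        high_events["taxon_unit"], high_events["site"], high_events["month"]
    ):
        grp = meta[(meta["site"] == site) & (meta["month"] == month)]
        for pos, pos_grp in grp.groupby("position", sort=False, observed=True):
            names = [n for n in pos_grp.index if n in idx_unit.columns]
            if not names:
                continue
            values.setdefault(str(pos), []).append(
                float(idx_unit.loc[taxon, names].mean())
            )
    return {p: np.asarray(v) for p, v in values.items()}
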