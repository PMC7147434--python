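"""eDNA index, nMDS ordination and PERMANOVA variance partitioning.

The eDNA abundance index (Wisconsin double standardization) feeds a
Bray-Curtis dissimilarity matrix; nMDS embeds one site-month's replicates
in two dimensions, and PERMANOVA apportions community variance among site,
month and transect position.
"""

import warnings

import ednahalo as eh

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table, _ = eh.simulate_study(
        eh.puget_sound_design(seed=0, n_asvs_per_phylum=6)
    )
    table = table.environmental()
    idx = eh.edna_index(table, grouping="asv")
    print(f"index matrix: {idx.shape[0]} taxa x {idx.shape[1]} replicates, "
          f"row maxima all {idx.max(axis=1).min():g}")

    meta = table.meta
    one = meta[(meta["site"] == "CI") & (meta["month"] == "May")]
    D = eh.bray_curtis(idx[list(one.index)], axis="columns")
    res = eh.nmds(D, dims=2, max_starts=50, seed=0)
    print(f"nMDS (CI, May): stress = {res.stress:.3f} "
          f"after {res.n_starts} random starts")

    D_all = eh.bray_curtis(idx[list(meta.index)], axis="columns")
    perm = eh.permanova(D_all, meta[["site", "month", "position"]],
                        ["site", "month", "position"], n_perm=999, seed=0)
    for _, row in perm.table.iterrows():
        if row["term"] in ("site", "month", "position"):
            print(f"PERMANOVA {row['term']:>9}: R2 = {row['r2']:.3f}, "
                  f"p = {row['p']:.3f}")
# R2 is each factor's share of Bray-Curtis variance (sequential sums of
# squares); p comes from 999 free permutations, so 0.001 is the smallest
# attainable value.
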