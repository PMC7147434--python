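"""Detecting the spatial halo of dinoflagellate depletion around eelgrass.

High-abundance (taxon, transect) events are isolated with an exact 1-D
two-cluster split, their per-position index values are clustered with a
two-component Gaussian mixture, and a rank-sum test quantifies the
separation between the eelgrass-adjacent group and bare substrate; a
Kruskal-Wallis check confirms the pattern is not spatial autocorrelation.
"""

import warnings

import ednahalo as eh
from ednahalo.pipeline import _position_values

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table, truth = eh.simulate_study(eh.puget_sound_design(seed=0))
    table = table.environmental()
    meta = table.meta
    idx_unit = eh.edna_index(table, grouping="taxon_unit")
    tax = table.taxonomy
    units = sorted(set(tax.loc[tax["phylum"] == "Dinoflagellata", "taxon_unit"])
                   & set(idx_unit.index))

    events = eh.transect_events(idx_unit, meta, units)
    events, ve = eh.split_high_low(events)
    high = events[events["abundance_class"] == "high"]
    print(f"{len(events)} (taxon, site-month) events; {len(high)} high-abundance "
          f"(between/total SS = {100 * ve:.1f}%)")

    values = _position_values(idx_unit, meta, high)
    res = eh.gmm_two_group(values, seed=0)
    print("position clusters:",
          ", ".join(f"{p}={c}" for p, c in res.position_cluster.items()))
    print(f"rank-sum p (group A vs B values) = {res.rank_sum_p:.2g}; "
          f"between-cluster variance = {100 * res.variance_explained:.1f}%")

    idx_asv = eh.edna_index(table, grouping="asv")
    pairs, H, p = eh.adjacent_dissimilarity_check(idx_asv, meta)
    print(f"spatial autocorrelation control: Kruskal-Wallis p = {p:.2f} "
          f"over {len(pairs)} adjacent-position pairs")
# A detected halo shows Eg through 15 m in cluster A with Ba alone in B and
# a small rank-sum p, while the autocorrelation p stays large (community
# turnover does not scale with alongshore spacing).
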