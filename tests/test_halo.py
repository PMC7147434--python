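"""Halo detection: event extraction, 1-D clustering, mixture grouping and
the spatial-autocorrelation control."""

import warnings

import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_two_cluster, exact_rank_sum_p
from ednahalo.halo import (
    adjacent_dissimilarity_check,
    gmm_two_group,
    rank_sum_test,
    split_high_low,
    transect_events,
)
from ednahalo.io_config import _meta_frame, DEFAULT_DIALECT


def _events(values):
    return pd.DataFrame(
        {
            "taxon_unit": [f"t{i}" for i in range(len(values))],
            "site": "CI",
            "month": "May",
            "mean_index": values,
        }
    )


class TestTransectEvents:
    def test_grand_mean_over_replicates(self):
        names = ["CI_Al_1_May_1_run1", "CI_Al_3_May_1_run1"]
        meta = _meta_frame(names, DEFAULT_DIALECT)
        idx = pd.DataFrame([[0.2, 0.4]], index=["tx"], columns=names)
        ev = transect_events(idx, meta, ["tx"])
        assert len(ev) == 1
        assert ev["mean_index"].iloc[0] == pytest.approx(0.3)

    def test_absent_taxon_warns_without_events(self):
        names = ["CI_Al_1_May_1_run1"]
        meta = _meta_frame(names, DEFAULT_DIALECT)
        idx = pd.DataFrame([[0.2]], index=["tx"], columns=names)
        with pytest.warns(UserWarning, match="absent"):
            ev = transect_events(idx, meta, ["missing"])
        assert ev.empty

    def test_zero_mean_transect_emits_no_event(self):
        names = ["CI_Al_1_May_1_run1", "NR_Al_1_May_1_run1"]
        meta = _meta_frame(names, DEFAULT_DIALECT)
        idx = pd.DataFrame([[0.5, 0.0]], index=["tx"], columns=names)
        ev = transect_events(idx, meta, ["tx"])
        assert set(ev["site"]) == {"CI"}


class TestSplitHighLow:
    def test_obvious_outlier_isolated(self):
        ev, ve = split_high_low(_events([0.01, 0.02, 0.90]))
        high = ev.loc[ev["abundance_class"] == "high", "mean_index"]
        assert list(high) == [0.90]
        assert ve > 0.99

    def test_two_values_perfect_split(self):
        ev, ve = split_high_low(_events([0.0, 1.0]))
        assert set(ev["abundance_class"]) == {"low", "high"}
        assert ve == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_partition_optimum(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 1, int(rng.integers(3, 13)))
        ev, ve = split_high_low(_events(vals))
        labels, ve_oracle = brute_force_two_cluster(vals)
        assert ve == pytest.approx(ve_oracle, abs=1e-12)
        assert list(ev["abundance_class"]) == list(labels)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            split_high_low(_events([0.5, 0.5, 0.5]))


class TestGmmTwoGroup:
    def test_separable_positions_isolate_bare(self):
        rng = np.random.default_rng(0)
        vals = {p: rng.normal(0.05, 0.01, 8).clip(0) for p in
                ("Eg", "1", "3", "6", "10", "15")}
        vals["Ba"] = rng.normal(0.9, 0.02, 8)
        res = gmm_two_group(vals, seed=0)
        assert res.position_cluster["Ba"] == "B"
        assert (res.position_cluster.drop("Ba") == "A").all()
        assert res.rank_sum_p < 0.001
        assert res.variance_explained > 0.9

    def test_component_means_match_separated_clouds(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.1, 1e-4, 40)
        b = rng.normal(0.9, 1e-4, 40)
        res = gmm_two_group({"Eg": a, "Ba": b}, seed=0)
        assert res.component_means[0] == pytest.approx(a.mean(), abs=1e-3)
        assert res.component_means[1] == pytest.approx(b.mean(), abs=1e-3)

    def test_identical_values_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            res = gmm_two_group({"Eg": np.full(4, 0.3), "Ba": np.full(4, 0.3)})
        assert res.degenerate
        assert res.rank_sum_p == 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="4 values"):
            gmm_two_group({"Eg": np.array([0.1]), "Ba": np.array([0.9])})

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        vals = {"Eg": rng.normal(0.2, 0.1, 10), "Ba": rng.normal(0.7, 0.1, 10)}
        r1 = gmm_two_group(vals, seed=5)
        r2 = gmm_two_group(vals, seed=5)
        assert (r1.position_cluster == r2.position_cluster).all()
        assert r1.rank_sum_p == r2.rank_sum_p


class TestRankSum:
    def test_fully_ordered_groups_exact_p(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_one_versus_one_is_uninformative(self):
        assert rank_sum_test([1.0], [2.0]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, int(rng.integers(2, 7)))
        b = rng.normal(0.5, 1, int(rng.integers(2, 7)))
        assert rank_sum_test(a, b) == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)


class TestAdjacentDissimilarity:
    def _design(self, n_sites=3):
        sites = ("CI", "NR", "PG", "SK", "WB")[:n_sites]
        names = [
            f"{s}_Al_{p}_May_1_run1"
            for s in sites
            for p in ("1", "3", "6", "10", "15")
        ]
        return names, _meta_frame(names, DEFAULT_DIALECT)

    def test_spacing_categories_from_consecutive_positions(self):
        names, meta = self._design()
        rng = np.random.default_rng(0)
        idx = pd.DataFrame(
            rng.uniform(0, 1, size=(6, len(names))),
            index=[f"A{i}" for i in range(6)], columns=names,
        )
        pairs, H, p = adjacent_dissimilarity_check(idx, meta)
        assert set(pairs["spacing_m"]) == {2, 3, 4, 5}  # 1-3, 3-6, 6-10, 10-15

    def test_identical_profiles_give_p_one(self):
        names, meta = self._design()
        idx = pd.DataFrame(
            np.tile([[0.2], [0.8]], (1, len(names))),
            index=["A0", "A1"], columns=names,
        )
        pairs, H, p = adjacent_dissimilarity_check(idx, meta)
        assert p == pytest.approx(1.0)

    def test_too_few_spacing_groups_rejected(self):
        names = [f"CI_Al_{p}_May_1_run1" for p in ("1", "3", "6")]
        meta = _meta_frame(names, DEFAULT_DIALECT)
        rng = np.random.default_rng(1)
        idx = pd.DataFrame(
            rng.uniform(0, 1, size=(4, 3)),
            index=[f"A{i}" for i in range(4)], columns=names,
        )
        # spacings 2 and 3 exist -> two groups, fine; drop to one transect
        # with a single gap
        names1 = names[:2]
        idx1 = idx[names1]
        meta1 = meta.loc[names1]
        with pytest.raises(ValueError):
            adjacent_dissimilarity_check(idx1, meta1)
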