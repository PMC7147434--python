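"""eDNA index transform, Bray-Curtis, nMDS and PERMANOVA."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ednahalo.community import bray_curtis, edna_index, nmds, permanova
from ednahalo.io_config import ReplicateCountTable


def _table(records):
    return ReplicateCountTable(
        pd.DataFrame(records, columns=["asv_id", "sample_name", "count"])
    )


S1, S2 = "CI_Al_1_May_1_run1", "CI_Al_1_May_2_run1"


class TestEdnaIndex:
    def test_two_by_two_worked_example(self):
        # counts [[10, 90], [30, 70]]; column totals 40, 160
        # proportions [[0.25, 0.5625], [0.75, 0.4375]]
        # row maxima 0.5625, 0.75 -> index [[4/9, 1], [1, 7/12]]
        t = _table([("A", S1, 10), ("A", S2, 90), ("B", S1, 30), ("B", S2, 70)])
        idx = edna_index(t)
        assert idx.loc["A", S1] == pytest.approx(4 / 9)
        assert idx.loc["A", S2] == pytest.approx(1.0)
        assert idx.loc["B", S1] == pytest.approx(1.0)
        assert idx.loc["B", S2] == pytest.approx(7 / 12)

    def test_single_replicate_all_nonzero_taxa_at_one(self):
        t = _table([("A", S1, 10), ("B", S1, 90)])
        idx = edna_index(t)
        assert (idx[S1] == 1.0).all()

    def test_depth_rescaling_invariance(self):
        t1 = _table([("A", S1, 10), ("B", S1, 30), ("A", S2, 9), ("B", S2, 7)])
        t2 = _table([("A", S1, 20), ("B", S1, 60), ("A", S2, 9), ("B", S2, 7)])
        pd.testing.assert_frame_equal(edna_index(t1), edna_index(t2))

    def test_row_maxima_exactly_one_for_nonzero_taxa(self):
        rng = np.random.default_rng(0)
        recs = [
            (f"A{i}", f"CI_Al_1_May_{r}_run1", int(c))
            for i in range(8)
            for r, c in zip((1, 2, 3), rng.integers(1, 500, 3))
        ]
        idx = edna_index(_table(recs))
        assert np.allclose(idx.max(axis=1), 1.0)

    def test_phylum_grouping_sums_before_proportions(self):
        t = _table([("A", S1, 10), ("B", S1, 30), ("C", S1, 60),
                    ("A", S2, 5), ("B", S2, 5), ("C", S2, 90)])
        t.taxonomy = pd.DataFrame(
            {"phylum": ["P1", "P1", "P2"], "taxon_unit": ["A", "B", "C"]},
            index=pd.Index(["A", "B", "C"], name="asv_id"),
        )
        idx = edna_index(t, grouping="phylum")
        # P1 proportions: 0.4 and 0.1 -> index 1.0 and 0.25
        assert idx.loc["P1", S1] == pytest.approx(1.0)
        assert idx.loc["P1", S2] == pytest.approx(0.25)

    def test_all_zero_taxon_left_at_zero_with_warning(self):
        counts = pd.DataFrame(
            [("A", S1, 10.0)], columns=["asv_id", "sample_name", "count"]
        )
        t = ReplicateCountTable(counts)
        t.taxonomy = pd.DataFrame(
            {"phylum": ["P1", "P2"], "taxon_unit": ["A", "B"]},
            index=pd.Index(["A", "B"], name="asv_id"),
        )
        idx = edna_index(t, grouping="phylum")
        assert "P2" not in idx.index or (idx.loc["P2"] == 0).all()


class TestBrayCurtis:
    def test_disjoint_support_is_one(self):
        m = pd.DataFrame({"x": [1.0, 0.0], "y": [0.0, 1.0]})
        assert bray_curtis(m).loc["x", "y"] == pytest.approx(1.0)

    def test_identity(self):
        m = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        assert bray_curtis(m).loc["x", "y"] == pytest.approx(0.0)

    def test_formula_arithmetic(self):
        m = pd.DataFrame({"x": [1.0, 1.0], "y": [0.0, 1.0]})
        assert bray_curtis(m).loc["x", "y"] == pytest.approx(1 / 3)

    def test_symmetry_zero_diagonal_and_range_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            m = pd.DataFrame(rng.uniform(0, 10, size=(6, 8)))
            D = bray_curtis(m).to_numpy()
            assert np.allclose(D, D.T)
            assert np.allclose(np.diag(D), 0.0)
            assert (D >= 0).all() and (D <= 1).all()

    def test_negative_entries_rejected(self):
        m = pd.DataFrame({"x": [1.0, -1.0], "y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="non-negative"):
            bray_curtis(m)

    def test_all_zero_pair_is_zero_with_warning(self):
        m = pd.DataFrame({"x": [0.0, 0.0], "y": [0.0, 0.0], "z": [1.0, 0.0]})
        with pytest.warns(UserWarning, match="all-zero"):
            D = bray_curtis(m)
        assert D.loc["x", "y"] == 0.0
        assert D.loc["x", "z"] == 1.0


class TestNmds:
    def test_three_equidistant_points_embed_exactly(self):
        D = pd.DataFrame(1.0 - np.eye(3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = nmds(D, max_starts=20, seed=0)
        assert res.stress < 0.01

    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(9, 2))
        D = pd.DataFrame(squareform(pdist(P)))
        res = nmds(D, max_starts=50, seed=0)
        assert res.stress < 0.01

    def test_two_points(self):
        D = pd.DataFrame([[0.0, 0.7], [0.7, 0.0]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = nmds(D, dims=1, max_starts=5, seed=0)
        assert res.stress < 1e-6

    def test_too_few_points_rejected(self):
        D = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="points"):
            nmds(D, dims=2)


def _random_distance(rng, n=12, p=5):
    X = rng.uniform(0, 1, size=(n, p))
    M = pd.DataFrame(X.T, columns=[f"s{j}" for j in range(n)])
    return bray_curtis(M, axis="columns")


class TestPermanova:
    def test_r2_matches_vegan_adonis2(self, tmp_path):
        """Sequential R-squared must agree with vegan's adonis2 on the same
        distance matrix (independent reference implementation)."""
        rng = np.random.default_rng(5)
        D = _random_distance(rng)
        fac = pd.DataFrame(
            {"site": np.repeat(["a", "b", "c"], 4), "month": np.tile(["x", "y"], 6)},
            index=D.index,
        )
        res = permanova(D, fac, ["site", "month"], n_perm=99, seed=0)
        D.to_csv(tmp_path / "dist.tsv", sep="\t")
        fac.to_csv(tmp_path / "fac.tsv", sep="\t")
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            f'D <- as.dist(as.matrix(read.table("{tmp_path}/dist.tsv", sep="\\t", header=TRUE, row.names=1)))\n'
            f'fac <- read.table("{tmp_path}/fac.tsv", sep="\\t", header=TRUE, row.names=1)\n'
            'res <- adonis2(D ~ site + month, data=fac, permutations=99, by="terms")\n'
            f'write.table(data.frame(term=rownames(res), R2=res$R2), "{tmp_path}/out.tsv", sep="\\t", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t").set_index("term")
        assert res.r2("site") == pytest.approx(ref.loc["site", "R2"], abs=1e-9)
        assert res.r2("month") == pytest.approx(ref.loc["month", "R2"], abs=1e-9)
        assert res.r2("residual") == pytest.approx(ref.loc["Residual", "R2"], abs=1e-9)

    def test_r2_partition_sums_to_one(self):
        rng = np.random.default_rng(7)
        D = _random_distance(rng)
        fac = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c", "d"], 3)}, index=D.index
        )
        res = permanova(D, fac, ["g"], n_perm=49, seed=0)
        assert res.table["r2"].iloc[:-1].sum() == pytest.approx(1.0, abs=1e-9)

    def test_perfect_separation_reaches_minimum_p(self):
        # two internally identical groups, hugely separated
        X = np.vstack([np.zeros((6, 3)), np.full((6, 3), 10.0)])
        X[:, 0] += 0.001 * np.arange(12)  # break exact ties within groups
        M = pd.DataFrame(X.T, columns=[f"s{j}" for j in range(12)])
        D = bray_curtis(M, axis="columns")
        fac = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6}, index=D.index)
        res = permanova(D, fac, ["g"], n_perm=99, seed=0)
        assert res.p("g") == pytest.approx(0.01)  # (0 + 1) / (99 + 1)

    def test_single_level_factor_warns_and_gives_p_one(self):
        rng = np.random.default_rng(9)
        D = _random_distance(rng)
        fac = pd.DataFrame({"g": ["a"] * 12}, index=D.index)
        with pytest.warns(UserWarning, match="single level"):
            res = permanova(D, fac, ["g"], n_perm=49, seed=0)
        assert res.p("g") == 1.0
        assert res.r2("g") == 0.0

    def test_zero_variance_rejected(self):
        D = pd.DataFrame(np.zeros((5, 5)))
        fac = pd.DataFrame({"g": ["a", "a", "b", "b", "b"]}, index=D.index)
        with pytest.raises(ValueError, match="variance"):
            permanova(D, fac, ["g"], n_perm=9)

    def test_permutation_p_reproducible_under_seed(self):
        rng = np.random.default_rng(11)
        D = _random_distance(rng)
        fac = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 4)}, index=D.index
        )
        p1 = permanova(D, fac, ["g"], n_perm=99, seed=42).p("g")
        p2 = permanova(D, fac, ["g"], n_perm=99, seed=42).p("g")
        assert p1 == p2
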