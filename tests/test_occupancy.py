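"""Occupancy model: detection histories, posterior inference, presence
probabilities, culling."""

import warnings

import numpy as np
import pandas as pd
import pytest

from oracles import grid_posterior_means
from ednahalo.io_config import ReplicateCountTable
from ednahalo.occupancy import (
    asv_presence_probabilities,
    build_detection_histories,
    cull_asvs,
    fit_occupancy_models,
    presence_probability,
)


def _table(records):
    return ReplicateCountTable(
        pd.DataFrame(records, columns=["asv_id", "sample_name", "count"])
    )


def _simulate_histories(rng, n_bottles, K, psi, p11, p10, asv="A"):
    z = rng.random(n_bottles) < psi
    y = rng.binomial(K, np.where(z, p11, p10))
    return pd.DataFrame(
        {"asv_id": asv, "bottle_id": [f"b{j}" for j in range(n_bottles)],
         "y": y, "K": K}
    )


class TestDetectionHistories:
    def test_counts_detections_per_bottle(self):
        t = _table(
            [("A", "CI_Al_1_May_1_run1", 10), ("A", "CI_Al_1_May_2_run1", 3),
             ("B", "CI_Al_1_May_1_run1", 7),
             ("B", "CI_Al_1_May_3_run1", 2)]
        )
        hist = build_detection_histories(t).set_index(["asv_id", "bottle_id"])
        assert hist.loc[("A", "CI_1_May"), "y"] == 2
        assert hist.loc[("A", "CI_1_May"), "K"] == 3
        assert hist.loc[("B", "CI_1_May"), "y"] == 2

    def test_zero_history_retained_for_absent_asv(self):
        t = _table(
            [("A", "CI_Al_1_May_1_run1", 10), ("A", "CI_Al_3_May_1_run1", 5),
             ("B", "CI_Al_3_May_1_run1", 5)]
        )
        hist = build_detection_histories(t).set_index(["asv_id", "bottle_id"])
        assert hist.loc[("B", "CI_1_May"), "y"] == 0
        assert hist.loc[("B", "CI_1_May"), "K"] == 1

    def test_replicate_attrition_reduces_K(self):
        t = _table(
            [("A", "CI_Al_1_May_1_run1", 10), ("A", "CI_Al_1_May_2_run1", 5)]
        )
        hist = build_detection_histories(t)
        assert (hist["K"] == 2).all()

    def test_detection_threshold_applies(self):
        t = _table([("A", "CI_Al_1_May_1_run1", 1), ("A", "CI_Al_1_May_2_run1", 9)])
        hist = build_detection_histories(t, detect_threshold=5)
        assert hist["y"].iloc[0] == 1


class TestPresenceProbability:
    def test_closed_form_plug_in(self):
        # psi=0.5, p11=0.8, p10=0.1, K=3, y=0:
        # 0.5*0.2^3 / (0.5*0.2^3 + 0.5*0.9^3) = 0.004/0.3685
        expected = 0.004 / (0.004 + 0.5 * 0.729)
        got = presence_probability(0.5, 0.8, 0.1, 0, 3)
        assert got == pytest.approx(expected, abs=1e-15)
        assert got == pytest.approx(0.0109, abs=1e-3)

    def test_no_false_positives_makes_any_detection_conclusive(self):
        assert presence_probability(0.5, 0.8, 0.0, 1, 3) == pytest.approx(1.0)
        assert presence_probability(0.2, 0.6, 0.0, 3, 3) == pytest.approx(1.0)

    def test_certain_occupancy_regardless_of_history(self):
        for y in range(4):
            assert presence_probability(1.0, 0.8, 0.1, y, 3) == pytest.approx(1.0)

    def test_monotone_nondecreasing_in_detections(self):
        rng = np.random.default_rng(0)
        hist = _simulate_histories(rng, 50, 3, 0.6, 0.8, 0.05)
        fit = fit_occupancy_models(hist, draws=2000, burn_in=1000, seed=1)
        d = fit.draws_for("A")
        probs = [
            presence_probability(d[:, 0], d[:, 1], d[:, 2], y, 3).mean()
            for y in range(4)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(probs, probs[1:]))


class TestFit:
    def test_saturated_histories_give_high_psi_and_p11(self):
        hist = pd.DataFrame(
            {"asv_id": "A", "bottle_id": [f"b{i}" for i in range(50)],
             "y": 3, "K": 3}
        )
        fit = fit_occupancy_models(hist, draws=3000, burn_in=1500, seed=0)
        row = fit.summary.iloc[0]
        assert row["psi_mean"] > 0.9
        assert row["p11_mean"] > 0.9

    def test_empty_histories_give_low_presence(self):
        hist = pd.DataFrame(
            {"asv_id": "A", "bottle_id": [f"b{i}" for i in range(50)],
             "y": 0, "K": 3}
        )
        fit = fit_occupancy_models(hist, draws=3000, burn_in=1500, seed=0)
        pres = asv_presence_probabilities(fit, hist)
        assert pres["A"] < 0.2

    def test_grid_oracle_agreement_small_instance(self):
        rng = np.random.default_rng(3)
        hist = _simulate_histories(rng, 25, 3, 0.6, 0.85, 0.05)
        fit = fit_occupancy_models(hist, draws=8000, burn_in=2000, chains=4, seed=0)
        mcmc = fit.summary.iloc[0][["psi_mean", "p11_mean", "p10_mean"]].to_numpy(float)
        grid = grid_posterior_means(hist["y"].to_numpy(), hist["K"].to_numpy())
        assert np.abs(mcmc - np.asarray(grid)).max() < 0.02

    def test_pattern_sharing_gives_identical_fits(self):
        rng = np.random.default_rng(4)
        h1 = _simulate_histories(rng, 30, 3, 0.5, 0.8, 0.05, asv="A")
        h2 = h1.copy()
        h2["asv_id"] = "B"  # same (K, y) multiset by construction
        fit = fit_occupancy_models(
            pd.concat([h1, h2], ignore_index=True), draws=1000, burn_in=500, seed=0
        )
        a = fit.summary.loc["A"].drop("converged")
        b = fit.summary.loc["B"].drop("converged")
        assert np.allclose(a.to_numpy(float), b.to_numpy(float))

    def test_ordering_constraint_enforced(self):
        rng = np.random.default_rng(5)
        hist = _simulate_histories(rng, 40, 3, 0.6, 0.9, 0.05)
        fit = fit_occupancy_models(hist, draws=2000, burn_in=1000, seed=0)
        d = fit.draws_for("A")
        assert (d[:, 2] < d[:, 1]).all()


class TestCull:
    def _table_with_asvs(self, asvs):
        recs = [(a, "CI_Al_1_May_1_run1", 10) for a in asvs]
        return _table(recs)

    def test_strict_threshold(self):
        t = self._table_with_asvs(["A", "B", "C", "D"])
        probs = pd.Series({"A": 0.05, "B": 0.19, "C": 0.20, "D": 0.9})
        out, log = cull_asvs(t, probs, threshold=0.2)
        assert sorted(out.asv_ids) == ["C", "D"]  # strictly below 0.2 removed
        assert log["n_asvs_removed"] == 2

    def test_zero_threshold_is_identity(self):
        t = self._table_with_asvs(["A", "B"])
        out, _ = cull_asvs(t, pd.Series({"A": 0.0, "B": 0.5}), threshold=0.0)
        assert sorted(out.asv_ids) == ["A", "B"]

    def test_threshold_one_keeps_only_certain(self):
        t = self._table_with_asvs(["A", "B"])
        out, _ = cull_asvs(t, pd.Series({"A": 0.999, "B": 1.0}), threshold=1.0)
        assert sorted(out.asv_ids) == ["B"]

    def test_keep_flag_overrides_cull(self):
        t = self._table_with_asvs(["A", "B"])
        keep = pd.Series({"A": True, "B": False})
        out, _ = cull_asvs(t, pd.Series({"A": 0.01, "B": 0.01}), 0.2, keep=keep)
        assert sorted(out.asv_ids) == ["A"]
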