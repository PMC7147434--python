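"""Bayesian site-occupancy filtering of ASVs with false-positive detection.

Each PCR replicate of a water bottle is an independent detection trial.
For one ASV, a bottle is truly occupied with probability ``psi``
(commonness); an occupied bottle yields a detection per trial with
probability ``p11`` (true-positive rate), an unoccupied one with ``p10``
(false-positive rate, e.g. index hopping or residual contamination).
Marginalizing the latent occupancy state z gives the per-bottle likelihood

    P(y | K) = psi * Binom(y; K, p11) + (1 - psi) * Binom(y; K, p10)

with y detections out of K surviving replicates. Priors are uniform on the
unit cube truncated to p10 < p11 (the standard identifiability constraint
for false-positive occupancy models). The posterior is sampled with a
random-walk Metropolis sampler, vectorized across ASVs, with reflective
proposals on (0, 1) and per-ASV step-size adaptation during burn-in.

The conditional presence probability for a bottle with history (y, K) is

    P(z=1 | y) = psi * p11^y (1-p11)^(K-y)
                 / [ psi * p11^y (1-p11)^(K-y) + (1-psi) * p10^y (1-p10)^(K-y) ]

averaged over posterior draws; an ASV's overall presence probability
aggregates its bottles (maximum by default) and ASVs below a probability
threshold (default 0.2) are culled from the count table.

Because the likelihood depends on the detection histories only through the
multiset of (K, y) pairs, ASVs sharing that multiset share a posterior; the
sampler fits each unique multiset once and maps results back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_config import ReplicateCountTable

__all__ = [
    "build_detection_histories",
    "fit_occupancy_models",
    "OccupancyResult",
    "presence_probability",
    "asv_presence_probabilities",
    "cull_asvs",
]

RHAT_LIMIT = 1.05


def build_detection_histories(
    table: ReplicateCountTable, detect_threshold: float = 1.0
) -> pd.DataFrame:
    """Detection histories per (ASV, bottle): y detections out of K trials.

    A detection is a replicate with at least ``detect_threshold`` reads.
    Bottles contribute K equal to their number of surviving replicates;
    (ASV, bottle) pairs with no detections are retained with y = 0 — they
    carry the information about psi and p10.
    """
    if detect_threshold < 1:
        raise ValueError("detect_threshold must be >= 1")
    env = table.environmental()
    meta = env.meta
    if meta.empty:
        raise ValueError("no environmental replicates in table")
    k_per_bottle = meta.groupby("bottle_id").size()
    empty = k_per_bottle[k_per_bottle == 0]
    if len(empty):  # pragma: no cover - groupby cannot produce zero groups
        warnings.warn(f"skipping bottles with no replicates: {list(empty.index)}")

    counts = env.counts
    det = counts[counts["count"] >= detect_threshold].copy()
    det["bottle_id"] = det["sample_name"].map(meta["bottle_id"])
    y = (
        det.groupby(["asv_id", "bottle_id"], sort=True)
        .size()
        .rename("y")
    )
    asvs = np.sort(counts["asv_id"].unique())
    bottles = k_per_bottle.index
    full = pd.MultiIndex.from_product([asvs, bottles], names=["asv_id", "bottle_id"])
    hist = y.reindex(full, fill_value=0).reset_index()
    hist["K"] = hist["bottle_id"].map(k_per_bottle).astype(int)
    hist["y"] = hist["y"].astype(int)
    if (hist["y"] > hist["K"]).any():  # pragma: no cover - defensive
        raise AssertionError("detections exceed trials")
    return hist


# ---------------------------------------------------------------------------
# sampler internals


def _reflect(x: np.ndarray) -> np.ndarray:
    """Fold real values into [0, 1] (reflective boundaries, symmetric)."""
    x = np.mod(x, 2.0)
    return np.where(x > 1.0, 2.0 - x, x)


def _pattern_matrix(hist: pd.DataFrame):
    """Per-ASV counts over unique (K, y) patterns.

    Returns (asv index, C [n_asv x n_patterns], K_pat, y_pat).
    """
    pat = hist.groupby(["asv_id", "K", "y"], sort=True).size().rename("n").reset_index()
    keys = sorted(set(zip(pat["K"], pat["y"])))
    key_ix = {k: i for i, k in enumerate(keys)}
    asvs = np.sort(hist["asv_id"].unique())
    asv_ix = {a: i for i, a in enumerate(asvs)}
    C = np.zeros((len(asvs), len(keys)))
    for a, K, y, n in pat.itertuples(index=False):
        C[asv_ix[a], key_ix[(K, y)]] = n
    Kp = np.array([k for k, _ in keys], dtype=float)
    yp = np.array([y for _, y in keys], dtype=float)
    return asvs, C, Kp, yp


def _log_lik(state: np.ndarray, C: np.ndarray, Kp: np.ndarray, yp: np.ndarray) -> np.ndarray:
    """Marginal log-likelihood for each unit; binomial coefficients dropped
    (constant in the parameters)."""
    psi = state[:, 0:1]
    p11 = state[:, 1:2]
    p10 = state[:, 2:3]
    b11 = p11 ** yp * (1.0 - p11) ** (Kp - yp)
    b10 = p10 ** yp * (1.0 - p10) ** (Kp - yp)
    mix = psi * b11 + (1.0 - psi) * b10
    return (C * np.log(np.maximum(mix, 1e-300))).sum(axis=1)


def _sample_chain(
    C: np.ndarray,
    Kp: np.ndarray,
    yp: np.ndarray,
    draws: int,
    burn_in: int,
    rng: np.random.Generator,
    target_accept: float = 0.3,
) -> np.ndarray:
    """One Metropolis chain over all units simultaneously; returns
    (draws, n_units, 3)."""
    n = C.shape[0]
    state = np.column_stack(
        [
            rng.uniform(0.05, 0.95, n),
            rng.uniform(0.5, 0.99, n),
            rng.uniform(0.01, 0.5, n),
        ]
    )
    state[:, 2] = np.minimum(state[:, 2], state[:, 1] - 1e-3)
    log_scale = np.full(n, np.log(0.1))
    ll = _log_lik(state, C, Kp, yp)
    out = np.empty((draws, n, 3))
    for t in range(burn_in + draws):
        prop = _reflect(state + rng.standard_normal((n, 3)) * np.exp(log_scale)[:, None])
        valid = prop[:, 2] < prop[:, 1]
        ll_prop = np.where(valid, _log_lik(prop, C, Kp, yp), -np.inf)
        accept = np.log(rng.random(n)) < (ll_prop - ll)
        state = np.where(accept[:, None], prop, state)
        ll = np.where(accept, ll_prop, ll)
        if t < burn_in:
            log_scale += 0.05 * (accept.astype(float) - target_accept)
        else:
            out[t - burn_in] = state
    return out


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat per unit and parameter; ``chains`` is
    (n_chains, draws, n_units, 3)."""
    n_chains, draws, n_units, n_par = chains.shape
    half = draws // 2
    segs = chains[:, : 2 * half].reshape(n_chains * 2, half, n_units, n_par)
    means = segs.mean(axis=1)
    variances = segs.var(axis=1, ddof=1)
    W = variances.mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / np.maximum(W, 1e-300))
    return rhat


@dataclass
class OccupancyResult:
    """Posterior summaries and draws for every fitted ASV.

    ``summary`` has one row per ASV with posterior mean and central 95%
    credible interval for psi, p11 and p10, plus the worst split-R-hat and a
    convergence flag. Draws are stored once per unique detection-history
    pattern; ``draws_for`` maps an ASV to its pooled (all chains) draws.
    """

    summary: pd.DataFrame
    _draws: np.ndarray  # (n_units, total_draws, 3)
    _unit_of_asv: pd.Series

    def draws_for(self, asv_id: str) -> np.ndarray:
        return self._draws[int(self._unit_of_asv.loc[asv_id])]


def fit_occupancy_models(
    histories: pd.DataFrame,
    draws: int = 5000,
    burn_in: int = 2000,
    chains: int = 2,
    seed: int = 0,
) -> OccupancyResult:
    """Fit the occupancy model to every ASV in a detection-history table.

    ``histories`` as produced by :func:`build_detection_histories`. ASVs
    whose history multisets coincide share a fit. Non-convergence
    (split-R-hat >= 1.05 on any parameter) is flagged, not fatal.
    """
    if histories.empty:
        raise ValueError("no detection histories to fit")
    asvs, C, Kp, yp = _pattern_matrix(histories)
    uniqC, unit_ix = np.unique(C, axis=0, return_inverse=True)
    rngs = np.random.default_rng(seed).spawn(chains)
    chain_draws = np.stack(
        [_sample_chain(uniqC, Kp, yp, draws, burn_in, r) for r in rngs]
    )  # (chains, draws, units, 3)
    rhat = _split_rhat(chain_draws).max(axis=1)  # worst over params, per unit
    pooled = chain_draws.transpose(2, 0, 1, 3).reshape(uniqC.shape[0], -1, 3)

    mean = pooled.mean(axis=1)
    lo = np.quantile(pooled, 0.025, axis=1)
    hi = np.quantile(pooled, 0.975, axis=1)
    rows = {}
    for j, par in enumerate(("psi", "p11", "p10")):
        rows[f"{par}_mean"] = mean[:, j][unit_ix]
        rows[f"{par}_lo"] = lo[:, j][unit_ix]
        rows[f"{par}_hi"] = hi[:, j][unit_ix]
    summary = pd.DataFrame(rows, index=pd.Index(asvs, name="asv_id"))
    summary["rhat"] = rhat[unit_ix]
    summary["converged"] = summary["rhat"] < RHAT_LIMIT
    if not summary["converged"].all():
        n_bad = int((~summary["converged"]).sum())
        warnings.warn(
            f"{n_bad} ASV fit(s) did not reach split-R-hat < {RHAT_LIMIT}; "
            "flagged and retained conservatively during culling"
        )
    unit_of_asv = pd.Series(unit_ix, index=asvs)
    return OccupancyResult(summary=summary, _draws=pooled, _unit_of_asv=unit_of_asv)


def fit_occupancy_model(histories: pd.DataFrame, **kwargs) -> OccupancyResult:
    """Single-ASV convenience wrapper around :func:`fit_occupancy_models`."""
    if histories["asv_id"].nunique() != 1:
        raise ValueError("expected histories for exactly one ASV")
    return fit_occupancy_models(histories, **kwargs)


def presence_probability(psi, p11, p10, y, K):
    """Conditional probability of true presence given a detection history.

    Accepts scalars (plug-in evaluation) or arrays of posterior draws
    broadcast against (y, K); averaging over draws is the caller's choice.
    """
    psi, p11, p10, y, K = map(np.asarray, (psi, p11, p10, y, K))
    num = psi * p11 ** y * (1.0 - p11) ** (K - y)
    den = num + (1.0 - psi) * p10 ** y * (1.0 - p10) ** (K - y)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0)
    return out if out.shape else float(out)


def asv_presence_probabilities(
    result: OccupancyResult,
    histories: pd.DataFrame,
    aggregation: str = "max",
) -> pd.Series:
    """Posterior presence probability per ASV, aggregated over its bottles.

    Per bottle, the conditional presence probability is averaged over
    posterior draws; ``max`` (default) or ``mean`` combines bottles into the
    single per-ASV value used for culling.
    """
    if aggregation not in ("max", "mean"):
        raise ValueError("aggregation must be 'max' or 'mean'")
    pat = (
        histories.groupby(["asv_id", "K", "y"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    out = {}
    for asv, grp in pat.groupby("asv_id", sort=True):
        d = result.draws_for(asv)  # (ndraws, 3)
        probs = np.array(
            [
                presence_probability(
                    d[:, 0], d[:, 1], d[:, 2], float(y), float(K)
                ).mean()
                for K, y in zip(grp["K"], grp["y"])
            ]
        )
        if aggregation == "max":
            out[asv] = probs.max()
        else:
            out[asv] = float(np.average(probs, weights=grp["n"]))
    return pd.Series(out, name="presence_prob").rename_axis("asv_id")


def cull_asvs(
    table: ReplicateCountTable,
    presence: pd.Series,
    threshold: float = 0.2,
    keep: Optional[pd.Series] = None,
) -> tuple[ReplicateCountTable, dict]:
    """Remove ASVs whose presence probability is strictly below ``threshold``.

    ``keep`` (e.g. the inverse of the convergence flag) forces retention of
    specific ASVs regardless of their estimate.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    low = presence.index[presence < threshold]
    if keep is not None:
        low = low.difference(keep.index[keep.astype(bool)])
    out_counts = table.counts[~table.counts["asv_id"].isin(low)]
    log = {
        "n_asvs_in": table.n_asvs(),
        "n_asvs_removed": int(
            table.counts.loc[table.counts["asv_id"].isin(low), "asv_id"].nunique()
        ),
        "threshold": threshold,
    }
    out = table.with_counts(out_counts, add_provenance="occupancy-filtered",
                            keep_all_samples=True)
    log["n_asvs_out"] = out.n_asvs()
    return out, log
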