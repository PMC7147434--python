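"""Synthetic eDNA metabarcoding study generator.

Emulates the statistical structure of a nearshore eelgrass transect survey:
five sites sampled in three months at seven transect positions (inside-bed
``Eg``, 1/3/6/10/15 m alongshore beyond the bed edge, and distant bare
substrate ``Ba``), with up to three PCR replicates per 1 L water bottle.

The generative model, per bottle:

1. latent relative abundances combine a Dirichlet base composition with
   log-normal site and month effects and episodic (taxon, site-month) bloom
   boosts;
2. one phylum (the dinoflagellate analogue) is multiplicatively depleted by
   ``halo_factor`` at positions Eg through 15 m, but not at Ba — the spatial
   "halo" the downstream modules are built to detect;
3. each (ASV, bottle) pair carries a latent occupancy state
   ``z ~ Bernoulli(psi_true)``; a replicate detects the ASV with probability
   ``p11_true`` when present and ``p10_true`` when absent;
4. detected ASVs receive multinomial reads at a negative-binomial replicate
   depth; positive controls are dominated by two control tissues with a small
   proportional leakage of environmental ASVs, and control tissue leaks back
   into field samples at a low rate (tag jumping).

Everything latent is returned in :class:`GroundTruth` so each downstream
stage can be validated against what actually happened.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_config import DEFAULT_DIALECT, NamingDialect, ReplicateCountTable

__all__ = ["SimulationParams", "GroundTruth", "puget_sound_design", "simulate_study"]

_DEFAULT_PHYLA = (
    "Dinoflagellata",
    "Bacillariophyta",
    "Chlorophyta",
    "Annelida",
    "Arthropoda",
    "Mollusca",
    "Ochrophyta",
    "Cnidaria",
)

# genus-level taxon units cycled over dinoflagellate ASVs, so several ASVs
# can share a unit (merged downstream to avoid pseudoreplication)
_DINO_GENERA = (
    "Heterocapsa",
    "Alexandrium",
    "Karlodinium",
    "Gymnodinium",
    "Protoceratium",
    "Kareniaceae",
)

CONTROL_ASVS = {
    "CTRL_KANGAROO": "control_kangaroo",
    "CTRL_OSTRICH": "control_ostrich",
}


@dataclass(frozen=True)
class SimulationParams:
    """Study design and generative-model parameters.

    Defaults describe the full survey design (5 sites x 3 months x 7
    positions x 3 PCR replicates = 105 bottles / 315 environmental
    replicates) with an injected tenfold dinoflagellate depletion at the
    eelgrass-adjacent positions.
    """

    sites: tuple[str, ...] = ("CI", "NR", "PG", "SK", "WB")
    months: tuple[str, ...] = ("May", "July", "August")
    positions: tuple[str, ...] = ("Eg", "1", "3", "6", "10", "15", "Ba")
    n_replicates: int = 3
    phyla: tuple[str, ...] = _DEFAULT_PHYLA
    n_asvs_per_phylum: int = 12
    base_concentration: float = 0.3
    site_effect_sd: float = 0.6
    month_effect_sd: float = 0.6
    bottle_effect_sd: float = 0.2
    halo_phylum: str = "Dinoflagellata"
    halo_factor: float = 10.0
    halo_positions: tuple[str, ...] = ("Eg", "1", "3", "6", "10", "15")
    bloom_prob: float = 0.07
    bloom_factor: float = 20.0
    read_depth_mean: float = 20000.0
    read_depth_dispersion: float = 5.0
    psi_true: float = 0.7
    p11_true: float = 0.9
    p10_true: float = 0.02
    contamination_rate: float = 0.01
    n_positive_controls: int = 3
    n_negative_controls: int = 2
    seed: int = 0

    def validate(self) -> "SimulationParams":
        if not self.sites or not self.months or not self.positions:
            raise ValueError("need at least one site, month and position")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_asvs_per_phylum < 1 or not self.phyla:
            raise ValueError("need at least one ASV")
        # closed bounds so degenerate diagnostic settings (psi=1, p11=1,
        # p10=0) stay expressible
        for name in ("psi_true", "p11_true", "p10_true"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not 0.0 <= self.bloom_prob < 1.0:
            raise ValueError(f"bloom_prob={self.bloom_prob} must lie in [0, 1)")
        if self.p10_true >= self.p11_true:
            raise ValueError("p10_true must be smaller than p11_true")
        if self.halo_factor < 1.0:
            raise ValueError("halo_factor must be >= 1")
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ValueError("contamination_rate must lie in [0, 1)")
        if self.read_depth_mean <= 0 or self.read_depth_dispersion <= 0:
            raise ValueError("read depth parameters must be positive")
        return self

    @property
    def n_bottles(self) -> int:
        return len(self.sites) * len(self.months) * len(self.positions)


def puget_sound_design(**overrides) -> SimulationParams:
    """The full survey design with optional field overrides."""
    return replace(SimulationParams(), **overrides).validate()


@dataclass
class GroundTruth:
    """Latent state of a simulated study."""

    true_proportions: pd.DataFrame  # bottles x ASVs, rows sum to 1
    z: pd.DataFrame  # bottles x ASVs, occupancy indicator in {0, 1}
    bloom_events: pd.DataFrame  # taxon_unit, site, month
    halo_phylum: str
    halo_positions: tuple[str, ...]
    halo_factor: float
    params: SimulationParams


def _taxonomy(params: SimulationParams) -> pd.DataFrame:
    rows = []
    i = 0
    for phylum in params.phyla:
        for j in range(params.n_asvs_per_phylum):
            asv = f"ASV_{i:04d}"
            if phylum == params.halo_phylum:
                genus = _DINO_GENERA[j % len(_DINO_GENERA)]
                family = genus if genus.endswith("aceae") else genus + "aceae"
                rows.append((asv, phylum, family, genus, genus))
            else:
                rows.append((asv, phylum, None, None, asv))
            i += 1
    for asv, unit in CONTROL_ASVS.items():
        rows.append((asv, "Chordata", "control", unit, unit))
    tax = pd.DataFrame(
        rows, columns=["asv_id", "phylum", "family", "genus", "taxon_unit"]
    )
    return tax.set_index("asv_id")


def _nb_depth(rng: np.random.Generator, params: SimulationParams, size: int) -> np.ndarray:
    r = params.read_depth_dispersion
    p = r / (r + params.read_depth_mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_study(
    params: SimulationParams, dialect: NamingDialect = DEFAULT_DIALECT
) -> tuple[ReplicateCountTable, GroundTruth]:
    """Simulate a full replicate-level count table plus its latent truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    tax = _taxonomy(params)
    env_asvs = [a for a in tax.index if a not in CONTROL_ASVS]
    n_asv = len(env_asvs)
    phylum = tax.loc[env_asvs, "phylum"].to_numpy()
    unit = tax.loc[env_asvs, "taxon_unit"].to_numpy()

    # base composition and design effects (log scale)
    base = rng.dirichlet(np.full(n_asv, params.base_concentration))
    base = np.maximum(base, 1e-12)
    site_eff = {
        s: rng.lognormal(0.0, params.site_effect_sd, n_asv) for s in params.sites
    }
    month_eff = {
        m: rng.lognormal(0.0, params.month_effect_sd, n_asv) for m in params.months
    }

    # episodic blooms of the halo phylum's taxon units per site-month
    dino_units = sorted(set(unit[phylum == params.halo_phylum]))
    bloom = {}
    bloom_rows = []
    for s in params.sites:
        for m in params.months:
            for u in dino_units:
                if rng.random() < params.bloom_prob:
                    bloom[(s, m, u)] = params.bloom_factor
                    bloom_rows.append((u, s, m))
    bloom_events = pd.DataFrame(bloom_rows, columns=["taxon_unit", "site", "month"])

    halo_mask = phylum == params.halo_phylum

    bottle_ids = []
    props_rows = []
    z_rows = []
    records: list[tuple[str, str, float]] = []
    names: list[str] = []

    run_of_site = {s: f"run{1 + i % 4}" for i, s in enumerate(params.sites)}

    for s in params.sites:
        for m in params.months:
            for pos in params.positions:
                w = base * site_eff[s] * month_eff[m]
                for u in dino_units:
                    if (s, m, u) in bloom:
                        w = np.where(unit == u, w * params.bloom_factor, w)
                w = w * rng.lognormal(0.0, params.bottle_effect_sd, n_asv)
                if pos in params.halo_positions:
                    w = np.where(halo_mask, w / params.halo_factor, w)
                props = w / w.sum()
                z = rng.random(n_asv) < params.psi_true

                bottle = f"{s}_{pos}_{m}"
                bottle_ids.append(bottle)
                props_rows.append(props)
                z_rows.append(z.astype(int))

                if pos == "Eg":
                    kind, pos_token = "Eg", dialect.eelgrass_position_token
                elif pos == "Ba":
                    kind, pos_token = "Ba", dialect.bare_position_token
                else:
                    kind, pos_token = "Al", pos
                for rep in range(1, params.n_replicates + 1):
                    name = f"{s}_{kind}_{pos_token}_{m}_{rep}_{run_of_site[s]}"
                    names.append(name)
                    p_det = np.where(z, params.p11_true, params.p10_true)
                    det = rng.random(n_asv) < p_det
                    depth = int(_nb_depth(rng, params, 1)[0])
                    if det.any() and depth > 0:
                        wd = props * det
                        counts = rng.multinomial(depth, wd / wd.sum())
                    else:
                        counts = np.zeros(n_asv, dtype=int)
                    # tag-jumping of control tissue into field samples
                    ctrl_leak = rng.poisson(
                        depth * params.contamination_rate / 20.0, len(CONTROL_ASVS)
                    )
                    nz = np.nonzero(counts)[0]
                    records.extend(
                        (env_asvs[i], name, float(counts[i])) for i in nz
                    )
                    records.extend(
                        (asv, name, float(c))
                        for asv, c in zip(CONTROL_ASVS, ctrl_leak)
                        if c > 0
                    )

    # positive controls: dominated by the two control tissues, with
    # proportional leakage of environmental ASVs following base composition
    mean_env = base / base.sum()
    for k in range(1, params.n_positive_controls + 1):
        name = f"POS_{params.months[0]}_{k}_run{1 + (k - 1) % 4}"
        names.append(name)
        depth = int(_nb_depth(rng, params, 1)[0])
        ctrl_w = np.array([0.6, 0.4]) * (1.0 - params.contamination_rate)
        w_full = np.concatenate(
            [mean_env * params.contamination_rate, ctrl_w]
        )
        counts = rng.multinomial(depth, w_full / w_full.sum())
        all_ids = env_asvs + list(CONTROL_ASVS)
        nz = np.nonzero(counts)[0]
        records.extend((all_ids[i], name, float(counts[i])) for i in nz)

    # negative controls: near-empty, trace contamination only
    for k in range(1, params.n_negative_controls + 1):
        name = f"NEG_{params.months[0]}_{k}_run{1 + (k - 1) % 4}"
        names.append(name)
        depth = rng.poisson(20)
        if depth > 0:
            counts = rng.multinomial(depth, mean_env)
            nz = np.nonzero(counts)[0]
            records.extend((env_asvs[i], name, float(counts[i])) for i in nz)

    counts_df = pd.DataFrame(records, columns=["asv_id", "sample_name", "count"])
    # ensure every sample (even an all-zero negative control) has metadata
    from .io_config import _meta_frame

    meta = _meta_frame(names, dialect)
    table = ReplicateCountTable(
        counts_df, meta=meta, taxonomy=tax, provenance=("raw", "synthetic"),
        dialect=dialect,
    )
    truth = GroundTruth(
        true_proportions=pd.DataFrame(props_rows, index=bottle_ids, columns=env_asvs),
        z=pd.DataFrame(z_rows, index=bottle_ids, columns=env_asvs),
        bloom_events=bloom_events,
        halo_phylum=params.halo_phylum,
        halo_positions=params.halo_positions,
        halo_factor=params.halo_factor,
        params=params,
    )
    return table, truth
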