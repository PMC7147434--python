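"""Reading/writing count tables, taxonomy and configuration.

Sample metadata is encoded in underscore-delimited sample names
(``SITE_KIND_POSITION_MONTH_REPLICATE_RUN``, e.g. ``WB_Al_1_July_2_run1``).
The vocabulary of site codes, transect kinds and months is configurable via
:class:`NamingDialect`; the defaults describe the Puget Sound eelgrass survey
design (sites CI, NR, PG, SK, WB; transect positions Eg, 1, 3, 6, 10, 15, Ba).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "POSITION_ORDER",
    "SampleNameError",
    "NamingDialect",
    "SampleMeta",
    "parse_sample_name",
    "ReplicateCountTable",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "Config",
    "load_config",
]

#: Ordered transect positions: inside the eelgrass bed (Eg), alongshore
#: distances in meters beyond the bed edge, and distant bare substrate (Ba).
POSITION_ORDER: tuple[str, ...] = ("Eg", "1", "3", "6", "10", "15", "Ba")

#: Numeric alongshore distance per position; Eg and Ba are off-axis (their
#: metric distance to the bed edge varies by site) and carry NaN.
POSITION_METERS: dict[str, float] = {
    "Eg": float("nan"),
    "1": 1.0,
    "3": 3.0,
    "6": 6.0,
    "10": 10.0,
    "15": 15.0,
    "Ba": float("nan"),
}


class SampleNameError(ValueError):
    """Raised when a sample name cannot be parsed under the active dialect."""


@dataclass(frozen=True)
class NamingDialect:
    """Vocabulary and field order of the underscore-delimited sample names."""

    field_order: tuple[str, ...] = (
        "site",
        "kind",
        "position",
        "month",
        "replicate",
        "run",
    )
    site_codes: tuple[str, ...] = ("CI", "NR", "PG", "SK", "WB")
    kind_codes: Mapping[str, str] = field(
        default_factory=lambda: {
            "Al": "alongshore",
            "Ac": "across",
            "Eg": "eelgrass",
            "Ba": "bare",
        }
    )
    months: tuple[str, ...] = ("May", "July", "August")
    #: leading tokens that mark control samples
    control_tokens: Mapping[str, str] = field(
        default_factory=lambda: {
            "POS": "positive_control",
            "NEG": "negative_control",
        }
    )
    eelgrass_position_token: str = "0"
    bare_position_token: str = "50"


DEFAULT_DIALECT = NamingDialect()


@dataclass(frozen=True)
class SampleMeta:
    """Design metadata for a single PCR replicate."""

    sample_name: str
    site: Optional[str]
    transect_kind: Optional[str]
    position: Optional[str]  # one of POSITION_ORDER for environmental samples
    distance_m: float
    month: Optional[str]
    bottle_id: Optional[str]
    replicate_index: int
    run_id: str
    sample_class: str  # environmental | positive_control | negative_control


def _parse_position(token: str, dialect: NamingDialect) -> str:
    if token == dialect.eelgrass_position_token or token == "Eg":
        return "Eg"
    if token == dialect.bare_position_token or token == "Ba":
        return "Ba"
    if token in POSITION_ORDER:
        return token
    raise SampleNameError(
        f"position field {token!r} is not a recognised transect position "
        f"(expected {dialect.eelgrass_position_token!r} [eelgrass], "
        f"{dialect.bare_position_token!r} [bare], or one of "
        f"{POSITION_ORDER[1:-1]})"
    )


def parse_sample_name(name: str, dialect: NamingDialect = DEFAULT_DIALECT) -> SampleMeta:
    """Parse an underscore-delimited sample name into :class:`SampleMeta`.

    Environmental names need at least ``len(dialect.field_order)`` fields;
    control names are ``POS_<month>_<replicate>_<run>`` (or ``NEG_...``).
    """
    fields = name.split("_")
    if fields and fields[0] in dialect.control_tokens:
        if len(fields) < 4:
            raise SampleNameError(
                f"control sample name {name!r}: expected 4 fields "
                "(TOKEN_month_replicate_run)"
            )
        token, month, rep, run = fields[0], fields[1], fields[2], fields[3]
        try:
            rep_i = int(rep)
        except ValueError:
            raise SampleNameError(
                f"sample name {name!r}: replicate field {rep!r} is not an integer"
            ) from None
        return SampleMeta(
            sample_name=name,
            site=None,
            transect_kind=None,
            position=None,
            distance_m=float("nan"),
            month=month,
            bottle_id=None,
            replicate_index=rep_i,
            run_id=run,
            sample_class=dialect.control_tokens[token],
        )

    if len(fields) < len(dialect.field_order):
        raise SampleNameError(
            f"sample name {name!r} has {len(fields)} underscore-delimited fields; "
            f"need at least {len(dialect.field_order)} "
            f"({'_'.join(dialect.field_order)})"
        )
    values = dict(zip(dialect.field_order, fields))

    site = values["site"]
    if site not in dialect.site_codes:
        raise SampleNameError(
            f"sample name {name!r}: unknown site code {site!r}; "
            f"allowed codes are {dialect.site_codes}"
        )
    kind_code = values["kind"]
    if kind_code not in dialect.kind_codes:
        raise SampleNameError(
            f"sample name {name!r}: unknown transect kind {kind_code!r}; "
            f"allowed codes are {tuple(dialect.kind_codes)}"
        )
    kind = dialect.kind_codes[kind_code]
    position = _parse_position(values["position"], dialect)
    if kind == "eelgrass" and position != "Eg":
        raise SampleNameError(
            f"sample name {name!r}: transect kind Eg requires position "
            f"{dialect.eelgrass_position_token!r}, got {values['position']!r}"
        )
    if kind == "bare" and position != "Ba":
        raise SampleNameError(
            f"sample name {name!r}: transect kind Ba requires position "
            f"{dialect.bare_position_token!r}, got {values['position']!r}"
        )
    month = values["month"]
    if dialect.months and month not in dialect.months:
        raise SampleNameError(
            f"sample name {name!r}: unknown month {month!r}; "
            f"allowed months are {dialect.months}"
        )
    try:
        rep_i = int(values["replicate"])
    except ValueError:
        raise SampleNameError(
            f"sample name {name!r}: replicate field {values['replicate']!r} "
            "is not an integer"
        ) from None
    if not 1 <= rep_i <= 3:
        raise SampleNameError(
            f"sample name {name!r}: replicate index {rep_i} outside 1-3"
        )
    return SampleMeta(
        sample_name=name,
        site=site,
        transect_kind=kind,
        position=position,
        distance_m=POSITION_METERS[position],
        month=month,
        bottle_id=f"{site}_{position}_{month}",
        replicate_index=rep_i,
        run_id=values["run"],
        sample_class="environmental",
    )


def _meta_frame(names: Iterable[str], dialect: NamingDialect) -> pd.DataFrame:
    rows = [dataclasses.asdict(parse_sample_name(n, dialect)) for n in names]
    meta = pd.DataFrame(rows).set_index("sample_name")
    meta["position"] = pd.Categorical(
        meta["position"], categories=list(POSITION_ORDER), ordered=True
    )
    return meta


class ReplicateCountTable:
    """ASV read counts per PCR replicate, with design metadata attached.

    Canonical storage is long format (``asv_id``, ``sample_name``, ``count``);
    zero counts are dropped internally. Counts are integer before
    decontamination and may be fractional afterwards (proportional subtraction
    is mapped back to the original replicate depth).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        meta: Optional[pd.DataFrame] = None,
        taxonomy: Optional[pd.DataFrame] = None,
        provenance: Sequence[str] = ("raw",),
        dialect: NamingDialect = DEFAULT_DIALECT,
    ):
        counts = counts.loc[:, ["asv_id", "sample_name", "count"]].copy()
        if (counts["count"] < 0).any():
            bad = counts.loc[counts["count"] < 0].iloc[0]
            raise ValueError(
                f"negative count {bad['count']} for ASV {bad['asv_id']!r} "
                f"in sample {bad['sample_name']!r}"
            )
        dup = counts.duplicated(subset=["asv_id", "sample_name"])
        if dup.any():
            bad = counts.loc[dup].iloc[0]
            raise ValueError(
                f"duplicate record for ({bad['asv_id']!r}, {bad['sample_name']!r})"
            )
        counts = counts[counts["count"] > 0].reset_index(drop=True)
        if meta is None:
            meta = _meta_frame(counts["sample_name"].unique(), dialect)
        self.counts = counts
        self.meta = meta
        self.taxonomy = taxonomy
        self.provenance = tuple(provenance)
        self.dialect = dialect

    # -- views ------------------------------------------------------------
    @property
    def asv_ids(self) -> np.ndarray:
        return np.sort(self.counts["asv_id"].unique())

    @property
    def sample_names(self) -> np.ndarray:
        return np.asarray(self.meta.index)

    def samples_of_class(self, sample_class: str) -> pd.Index:
        return self.meta.index[self.meta["sample_class"] == sample_class]

    def environmental(self) -> "ReplicateCountTable":
        keep = self.samples_of_class("environmental")
        return self.subset_samples(keep)

    def subset_samples(self, names: Iterable[str]) -> "ReplicateCountTable":
        names = pd.Index(names)
        return ReplicateCountTable(
            self.counts[self.counts["sample_name"].isin(names)],
            meta=self.meta.loc[self.meta.index.intersection(names)],
            taxonomy=self.taxonomy,
            provenance=self.provenance,
            dialect=self.dialect,
        )

    def replicate_totals(self) -> pd.Series:
        """Total reads per sample (zero for samples with no records)."""
        tot = self.counts.groupby("sample_name")["count"].sum()
        return tot.reindex(self.meta.index, fill_value=0.0)

    def wide(self, fill_value: float = 0.0) -> pd.DataFrame:
        """ASV x sample matrix, reconstructing dropped zeros."""
        w = self.counts.pivot_table(
            index="asv_id", columns="sample_name", values="count", fill_value=fill_value
        )
        return w.reindex(columns=self.meta.index, fill_value=fill_value)

    def with_counts(
        self,
        counts: pd.DataFrame,
        add_provenance: Optional[str] = None,
        keep_all_samples: bool = False,
    ) -> "ReplicateCountTable":
        """Replace the count records, optionally retaining metadata for
        samples whose every record was removed (keep_all_samples)."""
        prov = self.provenance + ((add_provenance,) if add_provenance else ())
        if keep_all_samples:
            meta = self.meta
        else:
            meta = self.meta.loc[self.meta.index.isin(counts["sample_name"].unique())]
        return ReplicateCountTable(
            counts, meta=meta, taxonomy=self.taxonomy, provenance=prov,
            dialect=self.dialect,
        )

    def total_reads(self) -> float:
        return float(self.counts["count"].sum())

    def n_asvs(self) -> int:
        return int(self.counts["asv_id"].nunique())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ReplicateCountTable({self.n_asvs()} ASVs x "
            f"{len(self.meta)} replicates, provenance={self.provenance})"
        )


_LONG_COLUMNS = {"asv_id", "sample_name", "count"}


def read_count_table(
    path: str | Path,
    taxonomy_path: Optional[str | Path] = None,
    dialect: NamingDialect = DEFAULT_DIALECT,
) -> ReplicateCountTable:
    """Read a TSV count table, long or wide format auto-detected.

    Long format needs columns ``asv_id``, ``sample_name``, ``count``; wide
    format is ASV rows x sample columns with the ASV identifier in the first
    column.
    """
    df = pd.read_csv(path, sep="\t")
    if _LONG_COLUMNS.issubset(df.columns):
        long = df.loc[:, ["asv_id", "sample_name", "count"]]
    else:
        first = df.columns[0]
        long = df.melt(id_vars=[first], var_name="sample_name", value_name="count")
        long = long.rename(columns={first: "asv_id"})
    long["count"] = pd.to_numeric(long["count"])
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None
    return ReplicateCountTable(long, taxonomy=taxonomy, dialect=dialect)


def write_count_table(
    table: ReplicateCountTable, path: str | Path, format: str = "long"
) -> None:
    if format == "long":
        out = table.counts.sort_values(["asv_id", "sample_name"])
        out.to_csv(path, sep="\t", index=False)
    elif format == "wide":
        table.wide().to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read an ASV -> phylum/family/genus table; derive ``taxon_unit``.

    ``taxon_unit`` merges redundant sequence variants: genus when assigned,
    else family, else the ASV id itself.
    """
    tax = pd.read_csv(path, sep="\t", dtype=str)
    if "asv_id" not in tax.columns or "phylum" not in tax.columns:
        raise ValueError("taxonomy table needs 'asv_id' and 'phylum' columns")
    if tax["asv_id"].duplicated().any():
        dup = tax.loc[tax["asv_id"].duplicated(), "asv_id"].iloc[0]
        raise ValueError(f"taxonomy lists ASV {dup!r} more than once")
    for col in ("family", "genus"):
        if col not in tax.columns:
            tax[col] = pd.NA
    if "taxon_unit" not in tax.columns:
        tax["taxon_unit"] = (
            tax["genus"].fillna(tax["family"]).fillna(tax["asv_id"])
        )
    return tax.set_index("asv_id")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class Config:
    """All pipeline thresholds and seeds, with documented defaults.

    Attributes
    ----------
    min_reads:
        Environmental replicates with fewer total reads are discarded
        ("extremely low number of reads"; the exact cutoff is a choice).
    detect_threshold:
        Reads needed to score a detection in an occupancy trial.
    occupancy_threshold:
        ASVs whose presence probability is strictly below this are culled.
    occupancy_aggregation:
        How per-bottle presence probabilities combine into one per-ASV value:
        ``max`` (default) or ``mean``.
    qc_alpha:
        One-sided tail mass for the replicate-dissimilarity cutoff.
    qc_pooling:
        ``pooled`` empirical quantile across all bottles (default) or
        ``normal`` parametric approximation.
    control_taxa:
        ``taxon_unit`` values treated as positive-control tissue (removed
        entirely during decontamination).
    permanova_terms / permanova_distance_as:
        Factor order for sequential variance partitioning; transect distance
        enters as a 7-level categorical factor by default, or continuous
        meters with ``continuous``.
    """

    min_reads: int = 1000
    detect_threshold: int = 1
    occupancy_threshold: float = 0.2
    occupancy_aggregation: str = "max"
    mcmc_draws: int = 5000
    mcmc_burn_in: int = 2000
    mcmc_chains: int = 2
    qc_alpha: float = 0.05
    qc_pooling: str = "pooled"
    n_permutations: int = 999
    permanova_terms: tuple[str, ...] = ("site", "month", "position")
    permanova_distance_as: str = "categorical"
    nmds_max_starts: int = 1000
    nmds_dims: int = 2
    control_taxa: tuple[str, ...] = ("control_kangaroo", "control_ostrich")
    halo_taxa_phylum: str = "Dinoflagellata"
    seed: int = 0
    record_timestamps: bool = False
    skip_stages: tuple[str, ...] = ()

    def validate(self) -> "Config":
        for name in ("occupancy_threshold", "qc_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if self.detect_threshold < 1:
            raise ValueError("detect_threshold must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.occupancy_aggregation not in ("max", "mean"):
            raise ValueError("occupancy_aggregation must be 'max' or 'mean'")
        if self.qc_pooling not in ("pooled", "normal"):
            raise ValueError("qc_pooling must be 'pooled' or 'normal'")
        return self


def load_config(path: Optional[str | Path]) -> Config:
    """Load a YAML config; missing keys fall back to defaults.

    Unknown keys produce a warning, not an error, so configs written for
    newer versions degrade gracefully.
    """
    if path is None:
        return Config().validate()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return Config().validate()
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k in known}
    for key in ("permanova_terms", "control_taxa", "skip_stages"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return Config(**kwargs).validate()
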