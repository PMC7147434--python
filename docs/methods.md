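# Methods

This note documents the statistical models implemented in `ednahalo`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter for
reproducibility.

## Study design and data model

The unit of observation is a PCR **replicate** (one of up to three
independent amplifications of a 1 L water **bottle**). Bottles sit on
transects at seven ordered positions: `Eg` (inside the eelgrass bed),
alongshore distances 1, 3, 6, 10 and 15 m beyond the bed edge, and `Ba`
(distant bare substrate). `Eg` and `Ba` have no fixed metric distance to the
bed edge (it varies by site), so they carry a categorical order but a NaN
alongshore coordinate; analyses that need meters (the spatial-autocorrelation
check) use only the 1–15 m positions. Sample metadata is parsed from
underscore-delimited sample names; the site/month/position vocabulary is
config-extensible with the five-site, three-month survey as default.

Counts are stored long-format (`asv_id`, `sample_name`, `count`), sparse by
dropping zeros, reconstructed on demand. Counts are integers until
decontamination, fractional afterwards.

## Decontamination

For each ASV, the maximum proportional representation across all
positive-control replicates (control tissue extractions) is subtracted from
that ASV's proportion in every field replicate, floored at zero, and mapped
back to the replicate's original read depth. Flooring at zero is the only
coherent reading of proportional subtraction; the removed mass is *not*
redistributed over the remaining ASVs, because the abundance index
renormalizes later and double normalization would distort the subtraction.
ASVs assigned to the control tissues themselves are removed from field
samples outright. Replicates below `min_reads` total reads (default 1000;
"extremely low" is inherently a judgment call) are then dropped.

## Occupancy model

Per ASV, bottles contribute independent histories (y detections out of K
surviving replicates; a detection is ≥ `detect_threshold` reads, default 1).
The latent state z (bottle truly occupied) is marginalized:

    P(y | K) = psi * Binom(y; K, p11) + (1 - psi) * Binom(y; K, p10)

Bottles with y = 0 are kept as trials — they carry the information about
psi and p10, and the model is degenerate without them. Priors are uniform
on (0, 1)³ truncated to p10 < p11, the standard constraint that breaks the
label-switching symmetry of false-positive occupancy models.

Sampling is random-walk Metropolis with reflective proposals on (0, 1)
(symmetric, so the acceptance ratio is the likelihood ratio), per-ASV step
sizes adapted toward 30% acceptance during burn-in and frozen afterwards.
Defaults: 2 chains × 5000 draws after 2000 burn-in. Convergence is
monitored by split-R̂ (< 1.05); non-convergent fits are flagged and the ASV
is retained through the cull regardless (conservative). Because the
likelihood depends on the histories only through the multiset of (K, y)
pairs, ASVs sharing that multiset share a posterior: the sampler fits each
unique multiset once, vectorized across all of them simultaneously, which
is what makes fitting thousands of ASVs cheap.

The per-bottle presence probability P(z=1 | y) is averaged over draws; an
ASV's overall presence probability is the **maximum** over its bottles
(default; the mean is available via `occupancy_aggregation`). Maximum is the
right default for a cull: an ASV convincingly present in even one bottle is
real. ASVs strictly below `occupancy_threshold` (default 0.2) are removed.
Posterior means were validated against brute-force grid integration (51³
cells) to |Δ| ≤ 0.02, and parameter recovery at psi = 0.6, p11 = 0.85,
p10 = 0.05 with 300 bottles is within ±0.07 with ≥ 85% credible-interval
coverage (see `tests/test_acceptance.py`).

## Replicate quality control

Each replicate is embedded as its eDNA-index vector; the bottle centroid is
the arithmetic mean of its replicates' vectors, and each replicate's
Bray–Curtis dissimilarity to the centroid is computed (singleton bottles:
distance 0 by convention; zero-read replicates: undefined, treated as
outliers). The discard cutoff is the **pooled** empirical 95th percentile of
centroid distances across the whole dataset (one-sided upper; `qc_alpha`
default 0.05). Pooling borrows strength across bottles that individually
hold only three replicates — a per-bottle interval from n = 3 would be
meaningless. A parametric normal approximation is available
(`qc_pooling: normal`) and is the automatic fallback below 10 distances.
QC is single-pass: centroids are not recomputed after discards. Centroids
live in index space, not principal-coordinate space; at K = 3 the
difference is negligible and the simpler choice is auditable.

Note the pooled empirical quantile flags ~5% of replicates *by
construction*, even on clean data; this mirrors a fixed-level QC rule, not
an outlier count estimate.

## eDNA abundance index

Counts (summed within the taxon group first, when aggregating to phylum or
taxon unit) → proportions within each replicate → each taxon row divided by
its row maximum. Equivalent to the Wisconsin double standardization. Every
non-empty taxon's row maximum is exactly 1; all-zero taxa stay at 0 with a
warning rather than NaN.

## Ordination and variance partitioning

Bray–Curtis distances on index vectors; pairs of two all-zero vectors get
distance 0 (with a warning) rather than NaN. Non-metric MDS minimizes
Kruskal stress-1 via SMACOF with isotonic regression (scikit-learn
backend), best of up to `nmds_max_starts` random starts (default 1000),
declaring convergence when a new start reproduces the incumbent best
configuration within Procrustes RMSE 1e-6.

PERMANOVA uses sequential (Type-I) sums of squares on the Gower-centered
squared-distance matrix: for nested design matrices X₀ ⊂ X₁ ⊂ … the term
SS is tr(HᵢG) − tr(Hᵢ₋₁G), residual SS = tr(G) − tr(H_full G), pseudo-F per
term, and p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1) under free row
permutation (default 999). R² terms plus residual sum to 1 exactly by the
telescoping construction. Term order follows the config (`site, month,
position` by default) and matters, as in any sequential decomposition.
Transect position enters as a 7-level categorical factor by default —
reporting a single R² for the term without asserting a linear distance
effect; a continuous-meters parametrization is available
(`permanova_distance_as: continuous`, which then excludes Eg/Ba). The
implementation agrees with vegan's `adonis2` to 1e-9 on shared fixtures
(tested via Rscript).

## Habitat association

Per phylum and site-month with both extremes sampled: mean index over Eg
replicates minus mean over Ba replicates (positive = eelgrass-associated).
Per phylum, the site-month values feed a two-sided paired Wilcoxon
signed-rank test — exact enumeration for n ≤ 12 without ties or zeros,
tie-corrected normal approximation otherwise — with Bonferroni correction
over the phyla actually tested (not a fixed count, since reduced designs
carry fewer phyla). Site-month is the pairing unit.

## Halo detection

1. **Events**: grand-mean index per (taxon unit, site-month), emitted where
   the taxon occurs. Taxon units merge redundant variants (genus, else
   family, else the ASV itself) to avoid pseudoreplication.
2. **High/low split**: exact two-cluster 1-D partition. For k = 2 in one
   dimension the optimal clusters are contiguous in sorted order, so
   scanning the n − 1 cut points is exhaustive — deterministic, and
   provably the k-means optimum (verified against full bipartition
   enumeration). Between/total SS is reported.
3. **Mixture grouping**: per-position mean index values of each high event,
   pooled across events (pooling across all sites and months is the
   default; per-transect fitting is possible by calling the function per
   event). Two-component univariate Gaussian mixtures with equal (`tied`)
   and unequal (`full`) variance are fit by EM (10 k-means++ restarts,
   seeded) and compared by BIC. Each position joins the component holding
   the majority of its values' mean posterior membership; group A is the
   component containing Eg, group B the other.
4. **Tests**: two-sided Wilcoxon rank-sum between the groups' pooled values
   (exact for min(n) ≤ 10 without ties; tie-corrected normal approximation
   *without* continuity correction otherwise, so identical groups give
   exactly p = 1). The spatial-autocorrelation control computes Bray–Curtis
   between adjacent alongshore positions (position-mean vectors, all ASVs),
   groups pairs by spacing in meters (2, 3, 4, 5 under the full design) and
   applies a Kruskal–Wallis rank test.

## Synthetic-data generator

The generator emulates the survey's statistical structure, not its
sequences: per bottle, a Dirichlet base composition (concentration 0.3 —
realistically uneven) with log-normal site, month and bottle effects
(SDs 0.6/0.6/0.2 on the log scale); episodic blooms as 20× boosts to one
dinoflagellate taxon unit per site-month with probability 0.07 (calibrated
so a survey carries a handful of high-abundance events); the halo as a
÷`halo_factor` (default 10) depletion of the dinoflagellate phylum at
positions Eg–15 m but not Ba; occupancy states z ~ Bern(ψ=0.7) per
(ASV, bottle) with per-replicate detection at p11 = 0.9 / p10 = 0.02;
negative-binomial replicate depths (mean 20 000, dispersion 5) with
multinomial reads over detected ASVs; positive controls dominated by two
control tissues with 1% proportional leakage of environmental ASVs, and a
small reverse leak of control tissue into field samples. No quantitative
contamination or dropout rates exist to copy, so those defaults are
order-of-magnitude choices recorded in the run manifest.

What it does **not** emulate — and therefore what passing tests do not
show about real data: sequence-level error (chimeras, index hopping
mechanics), taxonomic misassignment, unbalanced field sampling (every
bottle exists; the real survey lost some), run-level batch effects, and
taxon correlations beyond the bloom/halo structure. One consequence worth
knowing: because reads are compositional, a bloom that dominates a
replicate compresses the halo contrast (a 10× weight depletion shows up as
much less than 10× in proportions when the bloom taxon holds most of the
reads). The high-abundance selection preferentially picks exactly such
transects, so individual simulated surveys occasionally fail to isolate Ba
even with a strong injected halo; the acceptance suite therefore measures
recovery *rates* across seeded surveys (≥ 90% required) rather than
demanding success on every draw.

## Determinism and problem sizes

One master seed drives everything: per-stage seeds are derived by
`SeedSequence` spawning, so skipping a stage never shifts downstream
randomness, and a fixed master seed makes the full output directory
byte-identical across runs (manifest timestamps are off by default for this
reason; enable with `record_timestamps`). Seeds handed to third-party
backends are reduced below 2³¹.

Tests and the acceptance script run on deliberately scaled inputs chosen as
the package's own verification sizes: 8 phyla × 12 ASVs at depth 20 000 for
end-to-end recovery (50 seeded surveys per arm), 20 random history sets
against the 51³ grid oracle, 200 null simulations at 99 permutations for
test calibration, and 100 random instances for the 1-D cluster oracle.
The full suite runs in a few minutes on one CPU.

## Known limitations

- Per-ASV independent occupancy fits (no hierarchical pooling across ASVs,
  no covariates on detection); rare ASVs inherit diffuse posteriors.
- The eDNA index is relative: halo and habitat statements are about
  proportional representation, not absolute DNA concentration, and
  compositional closure can induce weak positive artifacts in non-depleted
  phyla when a depleted phylum is abundant.
- The "95% confidence interval" of the replicate QC is a pooled empirical
  quantile by choice; per-bottle or parametric variants change which
  replicates are discarded at the margin.
- PERMANOVA R² values are order-dependent (sequential SS); permuting term
  order is the caller's sensitivity analysis.
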