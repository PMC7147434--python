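# ednahalo

Post-sequencing analysis for replicate-level eDNA metabarcoding surveys of
seagrass habitat, built for the question: *does a taxon's abundance change
with distance from an eelgrass bed?* The package takes an ASV × PCR-replicate
count table (plus a taxonomy table) and carries it through decontamination,
Bayesian occupancy filtering, technical-replicate quality control, eDNA
abundance indexing, community ordination and variance partitioning,
phylum-level habitat-association tests, and a mixture-model procedure that
detects a spatial "halo" — depletion of a taxon (canonically, bloom-forming
dinoflagellates) inside a bed and out to tens of meters beyond its edge.

It is aimed at molecular-ecology groups running transect-structured eDNA
surveys with technical PCR replicates, and at anyone who wants a tested,
reusable implementation of these steps instead of one-off scripts. A
synthetic-study generator with full ground truth makes every stage testable
without sequencing data.

## The models at the core

**Occupancy filtering with false positives.** Each of the K PCR replicates of
a water bottle is an independent detection trial for an ASV. With commonness
ψ, true-positive detection rate p₁₁ and false-positive rate p₁₀ (p₁₀ < p₁₁),
the marginal likelihood of y detections in a bottle is

    P(y | K) = ψ · Binom(y; K, p₁₁) + (1 − ψ) · Binom(y; K, p₁₀)

Posteriors under uniform priors (truncated to p₁₀ < p₁₁) are sampled by a
vectorized Metropolis sampler; the conditional presence probability

    P(z = 1 | y) = ψ p₁₁^y (1−p₁₁)^(K−y) / [ψ p₁₁^y (1−p₁₁)^(K−y) + (1−ψ) p₁₀^y (1−p₁₀)^(K−y)]

is averaged over draws and ASVs with presence probability below 20% are
culled.

**eDNA abundance index.** Counts become within-replicate proportions, then
each taxon row is scaled so its maximum across replicates is 1 (the
Wisconsin double standardization). This removes read-depth and
amplification-efficiency differences and keeps values in [0, 1].

**Community structure.** Bray–Curtis dissimilarities BC(x, y) =
Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on index vectors feed non-metric MDS (Kruskal stress-1,
best of random starts) and a multi-factor PERMANOVA with sequential (Type-I)
sums of squares on the Gower-centered matrix — R² per factor, p-values by
free permutation. The implementation matches vegan's `adonis2` to machine
precision (tested).

**Halo detection.** Per (taxon, site-month) transect the grand-mean index
defines an event; events split into high/low abundance by an exact 1-D
two-cluster partition (provably the k-means optimum, no random restarts).
Pooled per-position values from high-abundance transects are clustered with
a two-component Gaussian mixture (equal/unequal variance chosen by BIC);
position groups are compared by Wilcoxon rank-sum, and a Kruskal–Wallis
check on adjacent-position dissimilarities rules out spatial
autocorrelation.

## Worked example

`examples/05_halo_detection.py` simulates the default survey (5 sites × 3
months × 7 transect positions {Eg, 1, 3, 6, 10, 15 m, Ba} × 3 PCR
replicates) with a tenfold dinoflagellate depletion injected at positions
Eg–15 m, then runs the halo procedure:

```
90 (taxon, site-month) events; 13 high-abundance (between/total SS = 77.5%)
position clusters: Eg=A, 1=A, 3=A, 6=A, 10=A, 15=A, Ba=B
rank-sum p (group A vs B values) = 8.3e-09; between-cluster variance = 88.4%
spatial autocorrelation control: Kruskal-Wallis p = 0.10 over 60 adjacent-position pairs
```

Reading this: the exact 1-D split isolates 13 bloom transects (the
between/total sum-of-squares ratio says how cleanly); the mixture model
groups every eelgrass-adjacent position (Eg through 15 m) away from bare
substrate (Ba), i.e. the depletion halo extends at least 15 m beyond the bed
edge; the tiny rank-sum p confirms the two groups differ; and the large
Kruskal–Wallis p shows community turnover does not scale with alongshore
spacing, so the halo is not a distance artifact. The other examples cover
simulation, the filtering chain, ordination/PERMANOVA, the phylum habitat
table, and the one-call `run_all` pipeline; each prints the numbers it
computes with a line on what they mean.

A thin CLI wraps the same library calls:

```sh
ednahalo simulate --seed 1 --outdir sim_out
ednahalo run-all --seed 1 --outdir run_out
```

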