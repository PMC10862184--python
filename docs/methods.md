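# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Abundant / rare partition and the descriptive layer

OTUs are classified by **mean relative abundance across all samples**,
computed after rarefaction: abundant > 0.1%, rare < 0.01%, strict
inequalities at both thresholds (a boundary value is moderate). Applying the
thresholds after rarefaction is a choice — the alternative (classify on raw
counts, then rarefy) changes borderline OTUs, and users comparing against
other studies should check which convention those used.

Rarefaction draws a multivariate hypergeometric sample (without
replacement), one draw per sample, seed recorded in every output header.
Samples below the target depth are dropped and logged.

α-diversity: Observed, Chao1 = S + F₁(F₁−1)/(2(F₂+1)), ACE with the
standard rare-abundance cutoff of 10 (if every rare taxon is a singleton,
coverage is zero and ACE falls back to Chao1), Shannon in nats, Simpson as
1 − Σp². Empty samples produce NaN, never silent zeros. Faith's PD sums the
branch lengths of the minimal subtree spanning a sample's tips **and the
root** — the rooted convention, so a single-taxon sample has PD equal to its
tip-to-root path; the alternative (most-recent-common-ancestor subtree) is a
one-line change but is not exposed as an option, to keep PD values
comparable across runs.

## Spatial statistics

Geographic distance is great-circle (haversine) with Earth radius
6371.0 km. The Mantel statistic is the Pearson correlation of the upper
triangles, with a permutation p-value over joint row/column reorderings of
the second matrix (999 permutations by default). When n! does not exceed
the permutation budget the test enumerates all permutations and the p-value
is exact — this makes the small-n behaviour deterministic and testable.
Missing environmental values are excluded pairwise. Environmental distance
for per-variable Mantel tests is the absolute difference of the variable
(the one-dimensional Euclidean distance); the choice matters little for
rank-like statistics but is recorded here because other toolchains sometimes
standardise first.

Levins niche breadth B = 1/Σp² uses each OTU's across-sample read shares;
it is invariant to scaling an OTU's counts and bounded by [1, n_samples].
Differential abundance is Kruskal–Wallis (with tie correction) per taxon at
phylum level within each abundance class, with Benjamini–Hochberg FDR across
taxa and significance at q < 0.01; constant taxa get p = 1 by convention.

## Assembly-process partitioning

The partition follows the phylogenetic-bin null-model framework: OTUs are
divided into bins (clades whose maximum within-clade patristic distance is
at or below a threshold, traversed greedily from the root; undersized bins
merge into the phylogenetically nearest bin by mean patristic distance and
are flagged), then every sample pair × bin receives two null-standardised
scores:

- **βNRI** — the z-score of abundance-weighted βMNTD against a null that
  relabels tips *within the bin*, abundances fixed. This within-bin shuffle
  is the single biggest modelling choice: a whole-tree shuffle would declare
  selection for any clade-confined community, including neutral ones.
  Consequence: two communities with identical support have βMNTD = 0 under
  the observed and every relabelled matrix, so sd_null = 0 and the score is
  undefined (flagged NaN), and selection on trait variation *between* bins
  is invisible by construction.
- **RC (Bray–Curtis)** — observed Bray–Curtis against null assemblages that
  preserve each sample's richness and total reads in the bin; species are
  drawn with probability ∝ occupancy frequency (Gumbel top-k), each drawn
  species starts with one individual, and the remainder fills multinomially
  ∝ total relative abundance.

Thresholds are hard-coded at ±1.96 (βNRI) and ±0.95 (RC). Classifications
aggregate with bin relative-abundance weights within each pair (renormalised
over scored bins), then average over pairs with equal weight; the five
fractions sum to 1 within 1e-9. Per-(pair, bin) seeds derive from the master
seed plus the pair/bin indices, so results do not depend on execution order.

**Binning defaults.** `distance_threshold = 1.7`, `min_bin_size = 36` on a
unit-depth tree — a handful of major clades, not many small bins. The power
of a pair-bin score grows with the number of taxa the two communities place
in the bin; at desk-scale richness (hundreds of OTUs), bins of ~25 taxa
leave βNRI and RC too noisy to recognise any non-neutral regime reliably,
which we verified by scanning bin sizes against the generator's known
regimes. Studies with 10⁴–10⁵ OTUs can and should use finer bins; both
parameters are ordinary configuration.

**Performance.** The null βMNTD exploits two exact identities: relabelling
tips is a joint permutation of the distance matrix, vectorised over a batch
of permutations; and any taxon present in both samples is its own nearest
neighbour (distance 0) under every relabelling, so only the support
set-difference is computed. Null assemblages fill reads with a single
batched multinomial per sample. A full 26-sample × 500-OTU × 1000-null
partition runs in about a minute on one CPU.

## Co-occurrence networks

SparCC: counts → Dirichlet(counts + 1) fraction resamples; per-pair
log-ratio variances from the covariance of logs; basis variances solved from
the sparsity-approximation linear system; ρᵢⱼ = (ωᵢ² + ωⱼ² − tᵢⱼ)/(2ωᵢωⱼ)
clamped to [−1, 1]; pairs with |ρ| above 0.1 iteratively excluded and the
system re-solved (up to 10 rounds, never disconnecting a component); the
estimate averages 20 resamples. Significance is a permutation bootstrap —
each replicate shuffles every OTU's counts across samples independently —
with two-sided p = (1 + #{|ρ*| ≥ |ρ̂|})/(1 + B), B = 100 by default.

Edges require |ρ| > 0.3 and p < 0.05. The keep-rule is *p below* the
threshold; a keep-rule of p above it would retain only non-significant
edges. Isolated nodes are dropped. Closeness is **harmonic** (sum of
reciprocal shortest-path lengths, disconnected pairs contribute 0,
normalised by n−1) because co-occurrence networks are routinely
disconnected and classic closeness is undefined there. Hubs rank by degree,
then harmonic closeness, then id. An explicit prevalence pre-filter (OTU
present in ≥ 1/3 of samples, configurable) controls sparsity before SparCC;
real surveys that report networks of ~10³ nodes from ~10⁴ OTUs must have
applied some such filter even when unstated.

Printed percentages round half-up to 1 decimal, or 2 decimals below 1% (so
164 of 26,308 prints as 0.62 and 24,230 of 26,308 as 92.1).

## The synthetic-data generator

The generator emulates the statistical structure of a two-layer,
multi-site soil amplicon survey: 13 sites × 2 layers, coordinates spanning
~500 km, a lognormal regional pool (sd 2.5 log units), rarefaction-depth
read totals (10,000 by default), clade-derived pseudo-phyla, and recorded
ground truth. Every regime adds a baseline demographic-drift term — a
per-sample lognormal perturbation exp(σ_d·z) of the pool before the
multinomial read draw, σ_d = 0.5. This term is essential, not cosmetic:
pure resampling noise from a shared pool produces communities far *more*
similar than any richness/occupancy-preserving null assemblage, so a "drift"
generator without it would be scored as homogenizing dispersal for every
pair. Ecological drift means independent compositional divergence of local
communities; σ_d sets its magnitude, and 0.5 places neutral communities in
the central band of both null models (the test suite asserts this
calibration).

Regimes, with defaults chosen once so that each pure regime is recognised
by the partition as itself (checked across ten independent master seeds):

- **drift** — the baseline noise only.
- **selection** (strength 5 = Gaussian filter width 0.2 sd) — traits evolve
  by Brownian motion with variance accruing only below root depth 0.25,
  i.e. conserved at the shallow-to-intermediate scale *inside* the bins the
  null model operates on; variance concentrated at the deepest splits would
  be factored out by within-bin randomisation and the regime would be
  unidentifiable. Traits are standardised; the two layers' optima anchor at
  the ±1.25 sd quantiles of the realised trait distribution, so both bands
  are populated whatever shape the Brownian draw took.
- **dispersal_limitation** (strength 2.0, range 25 km) — per-site lognormal
  pool perturbations with an exponential spatial kernel; both layers of a
  site share the site effect.
- **homogenizing_dispersal** (share 0.9) — 90% of each sample's reads are a
  single shared realised assemblage (mass effects overwhelming local
  drift); the rest is independent noise.
- **mixed** — selection and dispersal log-factors at half strength.

What the generator does **not** emulate: sequencing error and chimeras,
taxon-specific copy-number variation, genuinely correlated environmental
covariates, within-site plot structure, and the extreme richness of real
surveys. The last point matters most for interpretation: absolute abundance
thresholds (0.1% / 0.01%) partition a 500-OTU table very differently from a
26,000-OTU table (at 500 OTUs the *mean* OTU already sits at 0.2%), so the
distributional claims about abundant/rare structure are asserted at
study-scale richness in the tests, while the assembly and network machinery
is exercised at desk scale. Passing tests therefore show that the methods
recover known structure at desk scale, not that any particular field system
behaves like the generator.

Homogeneous selection deserves a caveat: detecting it requires presence
turnover among phylogenetically close taxa between identically-filtered
communities, which desk-scale richness largely saturates away. The
selection regime is therefore recognised mainly through heterogeneous
selection between the contrasted layers; the recovery check accordingly
sums the two selection fractions.

## Determinism and degenerate inputs

All randomness flows from explicit seeds through `numpy.random.Generator`;
child seeds derive via `SeedSequence` from the master seed plus structural
indices (sample pair, bin, replicate), so any subset of the work is
reproducible in isolation. Degenerate cases are flagged, never silently
zeroed: empty samples (α-diversity NaN), all-zero samples in Bray–Curtis
(NaN pairs), zero-variance Mantel inputs (NaN r), identical-support pairs in
βNRI (NaN score, excluded from weights), zero-total OTUs in niche breadth
(excluded, logged), and constant taxa in differential abundance (p = 1).

## Known limitations

- The within-bin taxa-shuffle null cannot see selection acting between
  bins; this is inherent to the framework, not an implementation limit.
- The Raup–Crick null's species draw uses occupancy only; with few samples
  and deep sequencing, occupancy saturates and carries little abundance
  information, which makes whole-community RC sensitive to the realised
  pool. Bin-level aggregation (as used here) is markedly more stable.
- SparCC assumes sparse true correlations; dense interaction structures
  bias the basis-variance solution.
- The pipeline treats the tree as error-free input; tree uncertainty is not
  propagated.
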