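# ecoassembly

Community-ecology analysis of amplicon surveys that partition a soil (or
other environmental) microbiome into **abundant** and **rare** taxa and ask
how each sub-community is assembled. The package implements, as one tested
pipeline:

- abundant / moderate / rare OTU classification by mean relative abundance
  (abundant > 0.1%, rare < 0.01%, strict inequalities),
- rarefaction, α-diversity (Observed, Chao1, ACE, Shannon, Simpson), Faith's
  phylogenetic diversity, Bray–Curtis dissimilarity,
- Mantel tests and distance-decay regression against great-circle distance
  and environmental distances, Levins niche breadth, and Kruskal–Wallis +
  Benjamini–Hochberg differential abundance between soil layers,
- phylogenetic-bin null-model partitioning of community assembly into five
  processes — heterogeneous selection, homogeneous selection, homogenizing
  dispersal, dispersal limitation and drift — from βNRI and modified
  Raup–Crick scores,
- SparCC compositional correlation networks with bootstrap significance,
  class-aware topology summaries and hub detection,
- a synthetic-data generator that produces OTU tables, trees, taxonomy and
  metadata under *known* assembly regimes, so every stage is testable
  without sequence data.

## The statistics at the core

For each sample pair and phylogenetic bin, the abundance-weighted
between-community mean nearest taxon distance is

βMNTD = ½ [ Σᵢ fᵢ · d(i, nearest taxon in the other community) + the
symmetric term ],

and βNRI is its z-score against a null that shuffles tip labels within the
bin, abundances fixed: βNRI = (βMNTD_obs − mean_null) / sd_null. The
modified Raup–Crick score compares observed Bray–Curtis to null assemblages
that preserve each sample's richness and total reads (species drawn ∝
occupancy, individuals filled ∝ total relative abundance): RC = 2·[P(null <
obs) + ½·P(null = obs)] − 1. Pairwise comparisons are classified as
homogeneous selection (βNRI < −1.96), heterogeneous selection (βNRI >
+1.96), homogenizing dispersal (RC < −0.95), dispersal limitation (RC >
+0.95) or drift (neither), aggregated with bin abundance weights; the five
fractions sum to 1.

SparCC estimates basis correlations from the log-ratio variances
t_ij = var(log xᵢ/xⱼ) = ωᵢ² + ωⱼ² − 2ρᵢⱼωᵢωⱼ under a sparsity assumption,
averaged over Dirichlet resamples (pseudo-count 1), with strongly
correlated pairs iteratively excluded; edges require |ρ| > 0.3 and a
bootstrap p < 0.05.

## Worked example

```python
import ecoassembly as ea
from ecoassembly.simulate import SimulationConfig

paths = ea.simulate_study(SimulationConfig(regime="dispersal_limitation",
                                           n_otus=300, seed=7), "demo")
table = ea.read_community_table(paths["table"])
tree = ea.read_tree(paths["tree"])
meta = ea.read_metadata(paths["metadata"])

table = ea.rarefy(table, depth=5000, seed=7)
cls = ea.classify_abundance(table)
print(cls.counts())
# {'abundant': 73, 'moderate': 101, 'rare': 126}

res = ea.distance_decay(ea.bray_curtis(table), ea.geographic_distance(meta),
                        n_permutations=999, seed=7)
print(round(res.mantel.r, 3), res.mantel.p, round(res.slope * 100, 4))
# 0.313 0.001 -0.054
```

The classification counts say that at 300 OTUs and this rarefaction depth 73
OTUs have mean relative abundance above 0.1% (desk-scale tables are far less
dominated than a real 26k-OTU survey, where the abundant class is below 1%
of OTUs). The Mantel correlation of 0.313 with permutation p = 0.001 and the
negative similarity slope (−0.054 per 100 km) recover the distance decay the
dispersal-limitation generator builds in; a `regime="drift"` run leaves the
same test non-significant.

The same pipeline runs from the shell:

```
ecoassembly simulate --regime drift --n-otus 300 --seed 7 --outdir demo
ecoassembly run --config config.yaml --seed 7 --outdir out
```

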