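# Methods

## The analysis

The unit of analysis is a locus, represented by its estimated gene tree: a
leaf-labeled tree with branch lengths in expected substitutions per site
and optional internal-edge support labels in [0, 100]. For each locus we
compute four branch statistics and two discordance responses, then ask
which statistics predict discordance and whether they are useful ranking
criteria for locus filtering.

### Branch statistics

- **CoV of root-to-tip distances.** The gene tree is midpoint-rooted (root
  at the midpoint of the longest leaf-to-leaf path) and the coefficient of
  variation (SD/mean) of the root-to-leaf path lengths is returned. Under
  a strict molecular clock the true tree is ultrametric and the CoV is 0;
  among-lineage rate variation and branch-length estimation error both
  raise it. The CoV is invariant to uniform rescaling of branch lengths,
  so it separates rate *heterogeneity* from overall rate. The SD uses the
  sample (n−1) denominator by default (`ddof=0` is available); with tens
  of tips the difference is cosmetic, but the worked fixtures record the
  sample convention.
- **Tree length** = sum of branch lengths; a proxy for the locus's overall
  substitution rate. In the pooled model across datasets of different
  sizes it enters as the **mean branch length** (tree length / number of
  branches) so values are on a common scale; per-dataset models use raw
  tree length.
- **Stemminess** = (sum of internal branch lengths) / (sum of terminal
  branch lengths). The aggregate-ratio reading was chosen over a mean of
  per-edge ratios; cumulative variants exist in the literature but the
  plain ratio is what the statistic's name says and is what we compute.
- **Mean branch support** = arithmetic mean of the numeric internal-edge
  labels (unlabeled edges are ignored, not treated as 0; a tree with no
  labels has a missing value).

The number of variable alignment columns (≥ 2 distinct unambiguous bases;
gaps and ambiguity codes never count as states) is computed for
completeness but is not part of the regression models — it tracks mean
branch support too closely to add information.

### Discordance responses

Topological distance is the Robinson–Foulds metric: the size of the
symmetric difference of the two trees' nontrivial bipartition sets,
normalized by its maximum, which is |B(t1)| + |B(t2)| in general and
2(n−3) for two binary trees on n shared leaves. Branch lengths are
ignored. Trees on unequal leaf sets are pruned to their shared taxa first
(at least 4 required). Multifurcating inputs are handled by letting the
denominator adapt; zero-length edges are *not* collapsed by default.

Each locus gets two responses: nRF to a **reference species tree**
(estimated from all loci of its dataset) and the **mean nRF to every other
locus** of its dataset (computed exactly, all pairs).

### Species-tree estimation

The reference tree and all subset re-estimates come from the same
summary-coalescent estimator: entry (a, b) of a distance matrix is the
mean, over gene trees containing both taxa, of the number of internal
nodes on the a–b path (node-count convention, degree-2 roots suppressed);
the topology is neighbor joining on that matrix. Averaged internode
distances converge to an additive distance on the species-tree topology
under the multispecies coalescent, so the estimator is statistically
consistent; the test suite verifies recovery of an 8-taxon species tree
with 0.5-coalescent-unit internal branches from 1000 clean gene trees in
20/20 replicates. Taxa are processed in sorted-label order, making the
estimate invariant to input order and to taxon permutations. Each internal
edge of the estimate is annotated with the fraction of input gene trees
containing its bipartition (in [0, 1]); the mean of these supports is the
tree's summary support. A `quartet_score` diagnostic (number of
(quartet, gene tree) agreements, enumerated for ≤ 20 taxa) aligns the
estimator with the quartet criterion optimized by ASTRAL, and an external
ASTRAL-style binary can be substituted via `external_astral_adapter`;
nothing in the package requires it.

### Regression models

Pooled model: response ~ cov_rtt + mean_branch_length + stemminess +
mean_support + dataset indicators, fit by OLS with classical standard
errors; the dataset indicators absorb between-dataset differences in both
response level and statistic scales (the fixed-effect "within"
formulation is exactly equivalent, which the tests verify via the
Frisch–Waugh identity). An optional weighted fit weights each locus by the
number of loci in its source dataset (or by its dataset's taxon count).
Predictors are left on their natural scale; t-statistics, being
scale-free, are the cross-predictor comparison currency. Two-sided
p-values, no multiple-testing correction across the four predictors.
Per-dataset models fit the same four predictors (raw tree length) twice
per dataset, once per response; loci with any missing value are dropped
listwise, and datasets with fewer than 6 complete loci are skipped.

### Filtering experiment

Loci are ranked by three metrics — nRF to the reference tree (a
topology-based control), CoV of root-to-tip distances, and mean branch
support — with "top" always the most favorable signal (low nRF, low CoV,
high support) and ties broken by locus id. For each metric and each
fraction in {20, 40, 60, 80}% we take the top-ranked and bottom-ranked
subsets, plus one random subset per fraction: 3 × 2 × 4 + 4 = 28 subsets
per dataset. Subset sizes use round-half-up; random draws are reproducible
from the experiment seed and recorded per record. Each subset's species
tree is scored by nRF to the reference tree and by its mean branch
support; per (metric, fraction) the top/bottom/random groups are compared
across datasets with a one-way ANOVA and Tukey HSD contrasts. The
reference tree always comes from the same estimator as the subsets, so
comparisons are estimator-consistent.

## The synthetic-data generator

`SimulationConfig` defines the study conditions; the defaults are the
conditions under which the package's end-to-end claims are tested.

| parameter | default | meaning |
| --- | --- | --- |
| n_datasets / n_taxa / n_loci | 10 / 16 / 200 | study size |
| birth_rate | 1.0 | Yule speciation rate (per coalescent-time unit) |
| branch_scale | 2.0 | stretches species-tree branches (ILS depth) |
| sigma_min, sigma_max | 0.0, 0.8 | per-locus rate-heterogeneity σ_ℓ ~ U |
| base_rate | 0.05 | substitutions/site per coalescent unit |
| locus_rate_log_sd | 0.5 | lognormal spread of per-locus overall rates |
| lambda0, lambda1 | 0.5, 4.0 | NNI error count k ~ Poisson(λ0 + λ1 σ_ℓ) |
| s0, beta | 98, 0.35 | supports centered at s0·e^(−βk) |
| support_noise_sd | 10 | per-edge Gaussian scatter of supports |
| missingness | 0.0 | Bernoulli holes in the presence matrix only |

Per dataset: an ultrametric Yule species tree (coalescent units); per
locus: a multispecies-coalescent gene tree (one haploid sample per
species, lineages coalescing at rate k(k−1)/2 within each species branch,
survivors passed rootward), branch lengths multiplied by
base_rate × locus rate × i.i.d. lognormal(−σ_ℓ²/2, σ_ℓ) multipliers
(mean 1, so σ_ℓ raises root-to-tip dispersion without changing expected
length), then k random NNI moves at uniformly chosen internal edges, then
per-edge supports clip(s0·e^(−βk) + N(0, noise), 0, 100). Seeding is
hierarchical (master → dataset → locus) and byte-reproducible.

Two defaults deserve their rationale:

- **branch_scale = 2.0.** ILS depth is not dictated by the design, so it
  was set to a moderate regime (average gene-tree/species-tree nRF ≈ 0.3)
  representative of curated phylogenomic datasets. The choice matters
  structurally: in the generator, topology error is Poisson in k given
  σ_ℓ, so conditional on k the responses carry no extra σ_ℓ signal, and
  mean support is a sharp (nonlinearly scaled) readout of k. Under very
  deep coalescent noise (scale 1) the CoV's partial effect in the pooled
  regression is positive but drowned; under moderate ILS it is clearly
  resolved. This is a statement about the generator, not about nature —
  which is precisely why the generator's link functions are documented as
  modeling choices that encode the empirical association between
  among-lineage rate variation and gene-tree conflict, not as mechanism.
- **support_noise_sd = 10.** Real per-edge supports scatter by tens of
  points within a tree; a token value would make the mean over ~n internal
  edges an almost noiseless function of k.

What the generator does **not** emulate: sequence-level estimation (error
is injected at the tree level by design), long-branch attraction or any
model misspecification, gene flow, duplication, recombination,
multi-individual sampling, or non-random missingness. Passing tests
therefore show that the pipeline detects the encoded rate-variation →
error association and that the estimators behave correctly — not that real
data must show the same effect sizes.

## Numerical conventions and edge cases

- Midpoint ties (several leaf pairs at the maximal path length) are broken
  by the lexicographically smallest sorted label pair; a midpoint landing
  exactly on a node (within 1e−12) roots at that node (degree-3 root
  allowed). Subdividing an edge preserves its total length to 1e−9.
  Multifurcating trees are accepted throughout.
- A tree with all-zero branch lengths has no midpoint (error); a
  zero-mean root-to-tip vector or zero terminal-branch sum likewise raise
  errors, which the table builder converts to missing values with logged
  warnings rather than aborting a whole dataset.
- Bipartitions are stored canonically (smaller side; lexicographic on
  ties), so split identity is independent of edge orientation. Trees with
  fewer than 4 leaves have no nontrivial bipartitions (empty set, not an
  error).
- Neighbor joining clamps negative branch lengths to zero; only the
  topology is consumed downstream (species-tree estimates carry unit
  branch lengths).
- The exact occupancy solver enumerates taxon subsets via a superset-sum
  sweep over presence bitmasks (guarded at 20 taxa, ~10⁶ subsets); ties
  prefer more taxa, then the lexicographically smallest taxon set. The
  greedy fallback peels the taxon/locus with the most missing entries
  (ties: taxa first, then lexicographic) and returns the best
  full-occupancy state encountered; it can never beat the exact solver.
- ANOVA treats within- and between-group sums of squares below a relative
  1e−12 tolerance as zero (F = 0, p = 1 for identical groups). Tukey HSD
  p-values come from the studentized-range distribution; for
  zero-variance groups the degenerate p is 1 (no difference) or 0.
- The pooled model refuses designs where a predictor is constant within
  every dataset, and rank-deficient designs raise an error naming the
  collinear columns.

## Problem sizes used in the checks

The end-to-end test conditions are the generator defaults above
(10 × 200 loci); estimator consistency uses 20 replicates of 1000
error-free gene trees on an 8-taxon caterpillar with 0.5-coalescent-unit
internal branches; the coalescent calibration uses 5000 three-taxon gene
trees against the closed-form discordance probability (2/3)e^(−t); the
null-size check redraws a standard-normal response 500 times over the
study's fixed predictors. Oracle equivalences (RF flood-fill, occupancy
enumeration, normal equations) run on hundreds of random small instances.

## Known limitations

- The summary estimator is a distance-based stand-in; it shares
  statistical consistency with quartet-median methods but not their
  optimality under few loci, and its supports are bipartition frequencies,
  not local posterior probabilities.
- "Dataset as a random factor" is implemented as fixed per-dataset
  intercepts. For the sign/significance questions asked here the two are
  interchangeable; variance components are out of scope.
- The per-locus weighting option follows dataset size in loci; weighting
  by taxon count is available but changes little because t-statistics are
  compared, not coefficients.
- Mean pairwise nRF is O(L²) per dataset; beyond a few thousand loci use
  the subsampling switch or expect minutes, not seconds.
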