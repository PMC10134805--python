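# Methods

## The data model

All analyses operate on a sparse binary presence matrix `X` with samples as
rows and genes as columns (`X[s, g] = 1` iff gene cluster `g` assembled in
sample `s`), a sample table mapping each sample to an *ecology* (sampled
environment class) and each ecology to an *ecology group*
(gut-associated / environmental / other host), and optionally an abundance
matrix on the same axes. Ids are ordered lexicographically at construction
so every seeded analysis is reproducible across platforms. A gene absent
from every sample does not exist in the catalog (no all-zero columns), and
samples with fewer than `min_genes` genes (default 100, the standard
catalog QC threshold) are dropped before analysis, with emptied columns
pruned afterwards to preserve the no-all-zero-column invariant.

## Between-ecology similarity by equal-depth subsampling

Ecology sample sizes in real catalogs differ by three orders of magnitude,
so raw gene-pool overlap would mostly measure sampling depth. The
comparison therefore subsamples to equal depth: per iteration, draw
`m` samples per ecology *without replacement* (the draw is of distinct
samples), take each ecology's gene pool as the union of its drawn samples'
gene sets, and compute all pairwise Jaccard distances plus, per ecology,
the number of genes found in no other ecology's pool. Defaults `m = 4` and
50 iterations follow the standard protocol; `m` is bounded by the smallest
ecology. Averaged distances are displayed after average-linkage
agglomerative ordering (the linkage criterion is not prescribed by the
protocol; average linkage is the neutral default, and complete/single are
available).

The permutation null permutes the sample → ecology assignment uniformly
while leaving each sample's gene content intact — the minimal
exchangeability-preserving null — and recomputes the subsampled distances
per permutation. The summary statistic is the **group gap**: mean
between-group distance minus mean within-group distance, so that planted
(or real) group structure yields a positive gap and the null distribution
is centred at zero. A gene → sample rewiring null (shuffling gene content
itself) would destroy per-sample gene counts and is intentionally not
implemented.

## Diversity

- Jaccard distance on gene sets: `1 − |A∩B|/|A∪B|`; undefined (an error)
  for two empty sets.
- Bray-Curtis on abundance vectors: `1 − 2Σmin(xᵢ,yᵢ)/(Σx + Σy)`.
  Deliberately *not* scale-invariant under one-sided rescaling; the
  within-ecology sweep therefore feeds it per-sample relative abundances
  (each row normalised to sum 1), while Chao1 receives raw integer counts.
- Chao1 / Chao2: the classic estimators `S_obs + f₁²/(2f₂)` on abundance
  singleton/doubleton counts (Chao1) or incidence unique/duplicate counts
  over sampling units (Chao2), with the bias-corrected fallback
  `S_obs + f₁(f₁−1)/2` when `f₂ = 0`. Non-integer abundances are rejected
  (the rare-class counts would be undefined). Chao2 requires at least two
  incidence units; since a single sample provides only one, the
  within-ecology sweep applies Chao2 to each ecology's m-sample incidence
  block per iteration. A per-sample Chao2 reading exists in the wild but is
  not well defined; the per-block reading is the one implemented, and
  Chao1 covers the per-sample axis from abundance data.

The within-ecology sweep reuses the equal-depth subsampling frame: per
iteration and ecology it pools all m(m−1)/2 pairwise Jaccard distances,
pairwise Bray-Curtis on relative abundances, per-sample Chao1 and the
block Chao2, in a long-format table.

## LSI sample clustering

TF-IDF weighting of the binary matrix:
`w(s,g) = [X(s,g)/rowsum(s)] · ln((n+1)/colsum(g))`. The `+1` in the IDF
numerator is part of the weighting definition used here; the logarithm is
natural — the base only rescales the matrix uniformly and the downstream
SVD directions are scale-invariant, but one base must be pinned for
bit-reproducibility. No additional TF smoothing is applied. Zero
rows/columns are invariant violations, not silently handled.

Truncated SVD (randomized solver, seeded) produces factor scores
`U·Σ` at rank k; UMAP (seeded, hence single-threaded and reproducible on a
fixed platform) reduces the scores to 2-D; HDBSCAN with a minimum cluster
size clusters the 2-D coordinates, labelling unassigned samples as noise
(−1). When a minimum cluster size exceeds the number of points, the result
is all-noise rather than an error — no cluster can reach the minimum.

The grid spans SVD k ∈ {10, 50, 100}, UMAP n_neighbors ∈ {10, 15, 20, 30}
and min_dist ∈ {0.1, 0.25, 0.5}, and minimum cluster size ∈
{25, 50, 75, 100}. Model selection formalises "maximise silhouette while
minimising unclustered samples", which is not a total order, as: restrict
to cells with noise fraction ≤ 10% (relaxing to the minimum achieved noise
fraction if none qualify), maximise silhouette among them, and break ties
toward fewer unclustered samples, then smaller minimum cluster size, k,
n_neighbors, min_dist. Silhouette is computed with the Euclidean metric on
the 2-D embedded coordinates over non-noise samples only (the embedding
space is the space that was clustered); with fewer than two clusters it is
NaN — an undefined sentinel, never 0, so degenerate cells cannot win the
grid while any defined cell exists.

Subclustering re-runs the full pipeline on the member samples of a chosen
parent cluster (rows restricted, emptied gene columns pruned, TF-IDF and
SVD re-fit on the restriction) with fixed defaults k = 50,
n_neighbors = 10, min_dist = 0.1, minimum cluster size 50.

## Enrichment statistics

Functional enrichment contrasts, per cluster and annotation value, the 2×2
table [genes with the annotation in/out of the cluster; genes with any
other annotation in/out]. The margins count *annotated genes* (the
annotation-count reading; unannotated genes do not enter the table). The
test is chi-square with 1 df without continuity correction, switching to a
two-sided Fisher exact test when any observed cell is below 6 — the Fisher
switch already guards small counts, so no Yates correction is layered on
top. Taxonomic enrichment compares per-sample counts of genes annotated to
a taxon between a cluster and all other clusters with a one-sided Welch
t-test (unequal variances are the norm across clusters); zero variance on
both sides with equal means reports p = 0.5, an uninformative taxon rather
than an error.

Benjamini-Yekutieli step-up adjustment
(`adj(i) = min_{j ≥ rank(i)} min(1, p(j)·n·c(n)/j)`, `c(n) = Σ 1/k`) is
applied within each feature-type family (all protein-product rows across
clusters form one family, COG rows another, taxon rows another); the
procedure is valid under arbitrary dependence, which matters because the
tests of a family share samples and margins. Significance requires
adjusted p < α (default 0.05) and fold change > 1.

## Conserved and ecology-set-specific genes

A pan-ecologically conserved gene is present in at least one sample of
every ecology — found in every metagenome *type*, though not necessarily
in every genome. Ecology-set candidates for a contrast (a proper subset of
ecologies vs the rest) must be present in ≥ 1 training sample of *each*
target ecology (the stricter reading of "prevalent in the ecologies of
interest", matching the shared-between language; a ≥ 1-in-*any* rule is
available as `prevalence_rule="any"`) and absent from every training
sample outside the target set. Candidates are validated on an independent
held-out sample set: one-sided test for higher abundance in target vs
background held-out samples, BY-adjusted across the candidates of the
contrast, selected at adjusted p < α. The default test is the one-sided
Mann-Whitney U — metagenomic abundances are heavy-tailed — with Welch's t
behind a config switch. Genes missing from the held-out matrix are never
selected: absence of evidence in validation blocks the claim. Held-out
prevalence/abundance profiles report, per ecology, the fraction of
held-out samples carrying each gene and the median/IQR abundance where
present; upset-style exact-membership counts summarise overlaps between
contrast results and always partition the union of the sets.

## The synthetic generator

`generate_catalog` plants, per sample: the conserved pool (each gene kept
with probability 1 − dropout), a draw from its group's core pool, a draw
from its ecology's exclusive pool, and fresh one-sample singleton genes
appended until the global singleton fraction reaches the configured target
(default 0.66, the empirical share of singleton gene clusters in large
catalogs; a target below what the structured pools already realize is an
explicit infeasibility error). Design choices that make the emulation
behave like real catalogs:

- **Singletons** are allocated to samples proportionally to structured
  gene count — deeper samples assemble more one-off genes.
- **Nested core windows**: an ecology draws its group-core genes from a
  prefix slice of the pool sized to its typical gene count, so gene-poor
  sites live on a genuinely smaller accessible pool (low richness) while
  still overlapping gene-rich sites of their group.
- **Sparse mucosal sites** (nasal/vaginal/airways analogues) get low core
  fractions and large exclusive pools, reproducing the
  highest-beta-diversity / lowest-richness signature of such sites.
- **Dropout** is independent per (sample, conserved/core gene): the
  simplest noise model under which conserved-gene recovery degrades
  gracefully.
- **Abundances** are lognormal(μ=1, σ=1) on the presence support; integer
  count mode adds `1 + Poisson(level)` for abundance-based richness.
  Planted contrast genes are shifted multiplicatively (default 8×) in
  their target ecologies.
- **Held-out samples** are drawn from the same generative process with
  fresh randomness and disjoint ids. Held-out *abundance* emulates
  read-mapping quantification against the catalog rather than per-sample
  assembly: a contrast gene can show abundance in background samples where
  it never assembled (detection probability configurable, default 1), so
  under a null shift of 1× the one-sided validation test is genuinely
  uniform rather than trivially significant.
- **Seed discipline**: one master seed; the catalog, abundance and
  held-out stages consume child streams spawned from it in a fixed order,
  so stages can be rerun independently yet reproducibly.

The default layout is 17 ecologies in 3 groups with 8 samples each;
ground truth (conserved/core/exclusive sets, group labels, realized
singleton fraction, planted contrasts) is recorded and re-validated
against the emitted matrix, and serialises to a plain-text file.

What the generator does **not** emulate: sequence content (no
nucleotides/ORFs), assembly chimerism or fragmentation, compositionality
of relative abundances, phylogenetic correlation between ecologies,
batch/study effects, or the heavy right tail of real per-sample gene
counts (10² – 10⁶). Passing recovery tests therefore demonstrates the
pipeline's correctness and statistical calibration under the planted
model, not performance on any real corpus.

## Run configuration schema

`genecat` subcommands read one YAML file; every key is optional and
defaults to the standard analysis settings:

```yaml
seed: 1                  # master seed (CLI --seed overrides)
min_genes: 100           # sample QC threshold
generator:               # synthetic-run parameters
  preset: default        # default (17 ecologies / 3 groups) | seven_group
  heldout_per_ecology: 4
  dropout: 0.05
  singleton_target: 0.66
subsample:
  m: 4
  iterations: 50
permutations: 0          # label permutations in the similarity stage
embedding:
  k_grid: [10, 50, 100]
  n_neighbors_grid: [10, 15, 20, 30]
  min_dist_grid: [0.1, 0.25, 0.5]
  min_cluster_grid: [25, 50, 75, 100]
  noise_fraction_max: 0.10
enrichment:
  alpha: 0.05
  fisher_cell_threshold: 6
contrasts:
  - name: gut_core
    target_ecologies: [human_gut, mouse_gut, cow_gut, pig_gut, chicken_cecum, moose_gut]
    alpha: 0.05
    prevalence_rule: each     # or any
    test: mannwhitney         # or welch
```

## Problem sizes in the test suite

Tests run the pipeline at sizes chosen to exercise the statistics, not the
engineering: 17 × 8 = 136-sample catalogs (≈ 9–10k genes) for similarity,
permutation (100 relabellings × 5 subsampling iterations) and conserved
recovery (50 seeds); ~510 samples for singleton-fraction fidelity; seven
planted groups × 100 samples with a reduced grid (k = 20,
n_neighbors ∈ {10, 15}, min_dist = 0.1, min cluster ∈ {25, 50}) over 20
seeds for clustering recovery; and 200 four-ecology replicates for the
null false-discovery check. The estimator oracle suite compares each
estimator with an independently written naive implementation on 1,000
random instances to 1e-12.

## Known limitations

- UMAP coordinates are reproducible only on a fixed platform (BLAS/numba
  versions); cross-platform bit-identity is guaranteed for every other
  artifact.
- The silhouette space (2-D embedding vs SVD scores) is a genuine
  degree of freedom in grid selection; 2-D is implemented and values are
  not comparable across the two conventions.
- The chi-square margins use annotation counts, not total gene counts;
  with sparse annotation the Fisher switch carries most of the load.
- Chao2 per-sample is not defined here (see above); consumers wanting
  sample-level richness should use Chao1 on counts.
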