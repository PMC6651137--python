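# Methods

## Problem

Complex neurodevelopmental disorders implicate hundreds of genes across
genomics (rare variants, GWAS hits, curated databases), epigenomics
(differential DNA methylation) and transcriptomics (differential
expression). Each evidence source is noisy and the reported gene lists
barely overlap, but truly involved genes tend to cluster in the
molecular interaction network. `netprop` turns this premise into a
pipeline: propagate tiered evidence over a high-confidence interactome,
score each gene by how much propagated evidence it carries *and* how
much its direct neighborhood carries, assess significance by
permutation, extract the significantly connected top-ranking module,
and characterize that module by topological clustering and
hypergeometric enrichment.

## Model

**Interactome.** An undirected graph over opaque gene identifiers.
Input edges carry integer confidence scores on the 0–1000 scale;
records of the same unordered pair are collapsed to the highest score,
then edges below the threshold (default 700, "high confidence") and
self-loops are dropped. Thresholding happens after collapse, so a pair
reported at (600, 800) survives at threshold 700. Diffusion runs on the
unweighted 0/1 adjacency A: confidence is used for inclusion only. The
operator is the symmetrically normalized adjacency
W = D^(-1/2) A D^(-1/2); rows/columns of isolated genes are zero, which
keeps gene indexing stable and gives isolated genes only the seed
retention term below. The spectral radius of W is at most 1.

**Evidence layers.** Each layer (default order G, E, T) has a major and
a minor tier, encoded in the genes-by-layers seed matrix X0 as 1, 0.5
and 0. A gene listed in both tiers of a layer is kept as major. Tier
definitions (e.g. methylation p-value bands, "differentially expressed
in at least two studies", database category cutoffs) are applied
upstream; this package consumes already-tiered lists. The layer count
is configurable: the single-layer variant (core genes = major,
peripheral genes = minor) is the same machinery with a 1-column X0.

**Diffusion.** X_{t+1} = α W X_t + (1−α) X0, iterated to the fixed
point Xss, equivalently (I − αW) Xss = (1−α) X0, which is nonsingular
for α < 1. Defaults: α = 0.7 (favors network smoothing while keeping
seed identity; the standard choice in the network-propagation
literature this package follows), max-norm tolerance 1e−6, iteration
cap 1e4. The closed-form solve is kept as an independent route and the
two agree to 10× the tolerance (tested).

**Composite score.** Columns of Xss are rescaled by their maxima (X*);
each gene's neighborhood term y*_ij is the mean of the top-m (default
m = 3) x* values among its direct neighbors in layer j (a gene is not
its own neighbor; fewer than m neighbors → mean over all; isolated → 0).
The final score d_i = (Σ_j x*_ij)(Σ_j y*_ij) rewards genes that both
receive evidence and sit in evidence-rich neighborhoods. Ties in top-m
selection are value-ties and cannot change the mean; neighbor order is
fixed (ascending gene identifier) for determinism.

**Permutation significance.** Whole gene rows of X0 are shuffled
(keeping each gene's cross-layer profile intact, which preserves
between-layer correlation under the null and makes the single-layer
case well defined), the full scoring is recomputed, and
p_i = (1 + #{perm: stat_i ≥ obs_i}) / (1 + P) with P permutations
(default 1000) — the add-one estimator, so p = 0 is unattainable and
min p = 1/(P+1). The statistic is either the composite d (multi-omics
analysis) or the raw steady-state score (single-layer analysis). For
networks up to 4000 nodes the resolvent (1−α)(I−αW)^(−1) is
precomputed densely once and each permutation is a matrix product;
larger networks fall back to iterative solves. Permutation streams are
spawned per permutation index from the one seed, so results are
independent of evaluation order.

**Core extension.** Non-core genes "comparable to the core" are those
significant at p < 0.05 whose score reaches the minimum core-gene
score (`min_core`, default) or a core-score quantile (`quantile:q`).
The comparability cutoff is exposed because no canonical definition
exists; `min_core` only selects anything when the core list contains
weakly connected members (as curated disease-gene lists do), which the
corresponding test reproduces by mixing scattered background genes
into the core.

**Module extraction.** Genes are ranked by descending d (ties
lexicographic). For each k in a grid (default 25–500 step 25), Ω(k) =
edges induced by the top-k genes is compared against R (default 999)
null draws; the empirical upper-tail p uses the add-one estimator and
a z-score records the deviation in null standard deviations. Three
nulls are provided:

- `degree_matched` (default): random gene sets matched to the top-k
  set's degree distribution via stratified draws over log2-degree
  bins. Degree is the dominant confounder of induced connectivity.
- `uniform`: unconstrained random gene sets.
- `ranking`: top-k sets of rankings recomputed from row-permuted seed
  matrices; additionally controls for the intrinsic smoothness of
  diffusion rankings.

The module is the top-k* genes where k* is chosen among sizes
significant at `alpha_nr` (default 0.01) by the `max_z` rule (default):
the size with the strongest z deviation. The alternative rules
`largest_k` (maximal size under the significance constraint) and
`min_p` are exposed. `max_z` is the default because empirical p-values
floor at 1/(R+1): on strongly modular inputs every candidate size ties
at the floor — high-degree genes and the local correlation of diffused
scores make *any* top-k set of a diffusion ranking more connected than
random sets — and the largest-significant-size rule then degenerates to
the grid maximum, while the z profile peaks near the true module scale.
No significant size yields an empty module as a diagnostic, not an
error. Connected components are reported with the largest first (size
ties toward the lexicographically smallest member).

**Communities and enrichment.** The module's largest connected
component is partitioned by five igraph method families (greedy
modularity, edge-betweenness removal, label propagation, leading
eigenvector, walktrap); every partition is scored by this package's own
Newman modularity Q = (1/2m) Σ_ij (A_ij − k_i k_j/2m) δ(c_i, c_j)
(0 for edgeless graphs by convention) and the best partition wins
(ties: fewer clusters, then input order). Per-cluster pathway
enrichment is the hypergeometric upper tail against a universe
defaulting to the interactome size (configurable to the GMT-annotated
gene count), BH-adjusted across the whole cluster-by-set table.
"Benjamini–Hochberg" is the interpretation used for q-values; strict
Bonferroni is exposed as an option. Per-cluster evidence-type
enrichment is the ratio of the supported fraction in the cluster to
the supported fraction in the module (1 = same proportion; undefined
when the module has no supported gene, reported as NaN).

All hypergeometric tails are computed with scipy's stable survival
function; the complement identity P(X ≥ k) + P(X ≤ k−1) = 1 holds to
1e−12 and exhaustive-enumeration agreement is tested for small
populations.

## Synthetic data

The generator emulates the statistical shape of the real inputs, not
their content:

- **Graph**: preferential attachment (default) or a configuration
  model with a truncated power-law (exponent 2.5) degree sequence;
  default 1000 genes, mean degree 10. Real interactomes at full scale
  are denser (mean degree ≈ 56); 10 keeps test-scale graphs sparse
  while preserving the heavy-tailed degree structure that stresses the
  resampling nulls. Realized mean degree is within 15% of the request
  at n ≥ 500 (tested).
- **Planted module**: a connected gene set (default 50) grown by
  random neighbor accretion, densified by adding random internal edges
  until the internal edge count reaches multiplier × max(initial
  count, background density × C(k,2)) — so planted density ≥
  multiplier × background density always holds, and multiplier 1 adds
  nothing beyond connectivity.
- **Evidence**: three layers; each planted gene is labelled major with
  probability 0.6 and minor with probability 0.2 per layer; background
  genes carry evidence at rate 0.02, split 30% major / 70% minor
  (mirroring the major fraction of curated disease-gene lists). These
  defaults are the package's reference benchmark conditions.

What the generator does **not** emulate: correlated noise between
layers beyond shared planted membership, multiple or overlapping true
modules, hub-biased evidence ascertainment, and identifier-mapping
noise. Passing recovery benchmarks therefore shows the machinery works
under a clean single-module signal, not that real multi-omics lists
are this well behaved.

With the defaults and a fixed seed the full pipeline recovers the
planted module with Jaccard ≈ 0.9–1.0 (seeds 0–5); with multiplier 1
and coverage equal to the background rate, recovery is at chance
(mean Jaccard ≤ 0.1 over 20 seeds), and recovery degrades
monotonically as background evidence noise rises — all asserted in the
test suite.

## Numerical and reproducibility choices

- One top-level seed drives everything; per-stage sub-seeds are
  derived by hashing the stage name, and per-permutation streams are
  spawned by index, so results are bit-reproducible and independent of
  evaluation order. Stochastic stages refuse to run without a seed.
- Dense resolvent precomputation is capped at 4000 nodes (128 MB);
  beyond that, iterative solves.
- Null p-value calibration is assessed on p-values pooled across
  independent replicate datasets, because all genes of one run share
  the same permutation draws and the single-run KS statistic is
  dominated by that correlation.
- Test and benchmark problem sizes (1000-gene graphs, 100–1000
  permutations, R = 99–999 resamples, 6 pooled replicates) are chosen
  to exercise every code path at interactive runtimes.

## Known limitations

- Scores are computed on the unweighted thresholded adjacency;
  confidence-weighted diffusion is deliberately out of scope.
- The degree-matched null bins degrees on a log2 scale; for very small
  networks the bins are coarse.
- Community detection on large, dense components can be slow for the
  edge-betweenness family; restrict `community_methods` if needed.
- Entrez/symbol mapping, isoform handling and database access are
  upstream of this package: all inputs must already share one
  identifier namespace.
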