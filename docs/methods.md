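# Methods

## Model and assumptions

The pipeline assumes the classical weighted co-expression model: genes form
modules whose members share a latent expression program, dependence between
profiles is captured by a similarity in [0, 1], and a soft power transform of
that similarity yields a weighted, unsigned network whose topology is
approximately scale-free.  Modules are branches of the UPGMA dendrogram of
the topological-overlap dissimilarity; genes on no accepted branch are
"grey" (unassigned, label 0).

Expression values must be pre-normalized and finite.  Missing values are
rejected at read time rather than imputed — the similarity and eigengene
computations have no principled treatment for them.

## Distance correlation

Similarity defaults to distance correlation (dCor), computed as the biased
V-statistic: double-centered Euclidean distance matrices A, B give
dCov² = mean(A∘B), dVar² = mean(A∘A), dCor = dCov/√(dVar_x·dVar_y).  dCor of
a constant vector is defined as 0 (the 0/0 convention of standard
energy-statistics software).  The α-exponent generalization and the
bias-corrected U-statistic are not offered.  Pairwise computation stores one
centered m×m matrix per gene, making every pairwise dCov² a dot product;
cost is O(n²m²) time and O(nm²) memory — fine for the few thousand genes a
CV filter leaves, and the reason that filter exists.  Absolute Pearson
correlation is the drop-in linear alternative.

## Soft-threshold selection

Connectivities k_i = Σ_{j≠i} a_ij (self-adjacency is excluded everywhere:
a_ii := 0) are binned into 10 equal-width bins; log10(bin frequency) is
regressed on log10(bin mean k); the fit index is −sign(slope)·R², so a
decaying distribution scores positive.  β is the smallest candidate
(default 1–20) with index ≥ 0.85 **and mean connectivity ≥ 1**.  The second
condition matters: as β grows, connectivity collapses toward zero and the
log-log fit improves spuriously, so without a floor the criterion can
"qualify" a vacuously sparse network.  When nothing qualifies — typical for
small synthetic data, whose planted-factor networks are not scale-free — the
pipeline warns and falls back to the conventional default unsigned power for
the sample count (6 for ≥ 40 samples, 7 for 30–39, 8 for 20–29, 9 below 20)
rather than maximizing the fit index, for the same reason.  The full
diagnostic table (β, signed R², mean/median/max k) is always returned.

## Clustering

UPGMA is delegated to scipy's linkage (deterministic; average linkage is
reducible, so merge heights are monotone).  The tree variant of dynamic tree
cut severs all merges above `cut_height` (default 0.99 × the maximum merge
height, or an absolute height) and accepts branches with at least
`min_module_size` leaves (default 30) as modules, numbered 1..k by
decreasing size (ties by first-gene index).  The hybrid variant with its
PAM-like stage is deliberately absent — the refinement stage below plays
that role with an explicit, global criterion.

## k-module refinement

Mean connectivity of gene i to module m is mc(i, m) = (1/n_m) Σ_{j∈S_m} a_ij.
The denominator is n_m even when gene i is itself a member (its self-term
contributes 0); a flag offers the n_m − 1 variant for sensitivity analysis.
Each iteration computes mc against the memberships frozen at the start of
the iteration (synchronous update — results are independent of gene order),
moves every eligible gene to the argmax module (ties to the lowest label),
and stops at zero changes or `max_iter` (default 100).  Grey genes are
frozen unless `reassign_grey` is set, and grey is never a target.  If a
module empties its id is retired with a warning — possible in principle,
but not observed on any planted-structure instance in the test suite.

## k-eigengene comparator

A module's eigengene is the first right singular vector (over samples) of
its gene-standardized submatrix, sign-fixed to correlate non-negatively with
the module mean profile; the first singular value's share of total variance
is reported as the eigengene's variance proportion.  The comparator
reassigns each gene to argmax_j |Pearson(g_i, eg_j)|, recomputing eigengenes
every iteration from current memberships, with the same synchronous
semantics.
Pearson (signed, absolute value taken) is the coherent choice here: distance
correlation is non-negative, which would make the absolute value vacuous.

## Convergence behaviour (a design finding)

The two refiners differ more than symmetrically:

* **k-eigengene cannot cycle.**  For standardized genes the first principal
  component maximizes the sum of squared gene–eigengene correlations of its
  members over all centered unit vectors, and the assignment step maximizes
  each gene's squared correlation with eigengenes fixed.  The sum
  Φ = Σ_g cor²(g, eg_label(g)) is therefore non-decreasing, and exact-tie
  moves strictly decrease labels under the lowest-label rule, so no label
  vector can recur.  (Infinite loops reported for eigengene-centroid k-means
  arise under Euclidean-distance assignment, for which PC1 centroids are not
  optimal, or under asynchronous updates.)
* **k-module can cycle.**  Synchronous mean-connectivity updates admit no
  such potential; a four-gene fixture (two anchors plus two movers sharing a
  latent direction) produces a genuine period-2 swap.  Both refiners
  therefore record label-vector recurrence: `oscillation_detected` is set
  and the run proceeds to `max_iter` instead of claiming convergence.  On
  planted-structure data k-module converged in every tested instance, in 1–3
  iterations.

## Synthetic data

The generator plants one standard-normal latent factor per module across
samples.  A member gene is loading·f + noise, with per-gene N(0, noise_sd²)
noise; optional anti-genes use −loading, and nonlinear genes use the
standardized even map (f² − 1)/√2, whose Pearson correlation with linear
module-mates is ≈ 0 while dCor remains substantial — the fixture that
motivates distance correlation.  Grey genes are i.i.d. normal with
sd = √(loading² + noise_sd²) so all genes share one marginal scale.
Defaults: 300 genes, 60 samples, 5 balanced modules, loading 0.9, noise sd
0.5, grey fraction 0.1 — a well-separated desk-scale instance (within-module
|Pearson| exceeds between-module by ≳ 0.3).  Everything derives from one
seed through a named generator; no global random state.

What the generator does **not** emulate: RNA-seq count noise (negative
binomial), sample outliers, batch structure, heterogeneous per-gene loadings,
correlated factors, or realistic scale-free topology — planted-factor
networks have near-homogeneous within-module connectivity, which is exactly
why the soft-threshold criterion falls back to its default power on them.
Passing tests demonstrate algorithmic correctness and recovery under the
stated model, not performance on real tissue data.

## Module preservation

Two partitions over the same genes are compared module-by-module with the
one-sided Fisher's exact test on the overlap (hypergeometric upper tail).
The tail is summed in log space from gammaln terms: identical 500-gene
modules in a 1000-gene universe have p ≈ 10⁻²⁹⁹, far below the smallest
positive double, yet their preservation significance −log10 p must stay
finite (reported values are capped at 10⁶).  A module counts as preserved
when its best significance over the other partition's non-grey modules
exceeds 50 (p < 10⁻⁵⁰); grey is excluded from counting.  For an unordered
pair of sample splits the count is taken with the earlier-indexed part as
the row partition.  Split-sample stability runs the entire pipeline
independently per fold and reports the mean and min–max range of
preservation counts over all fold pairs for each method (no refinement /
k-module / k-eigengene).

## Numerical choices and degenerate inputs

* Similarity/TOM matrices are symmetrized ((M + Mᵀ)/2) and clipped to [0, 1]
  against float fuzz; diagonals are exactly 1 (similarity, TOM) or 0
  (adjacency, dissimilarity).
* Constant genes: off-diagonal similarity 0 with a warning; they make a
  module's eigengene undefined (error naming the module).
* CV filtering uses the sample standard deviation (n − 1); genes with
  mean ≤ 0 have undefined CV and are excluded with a warning.  "Above-average
  intensity" means the gene's mean exceeds the grand mean of gene means.
  Thresholds are dataset-specific choices and have no default in the CLI.
* All argmax ties anywhere resolve to the lowest module label; all stochastic
  steps (sample splitting, simulation, corruption) take explicit seeds.

## Problem sizes

The test suite and the acceptance script run on the generator's default
scale (300 genes × 60 samples, with 10–20 replicate instances per property
and 2–5 sample splits), chosen so the whole battery completes in well under
a minute while keeping every module large enough for stable eigengenes and
meaningful Fisher tails.
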