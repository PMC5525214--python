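# Methods

## Distance model

Weighted UniFrac between two relative-abundance profiles p, q over the
leaves of a rooted phylogeny with branch lengths is computed as the
Earth Mover Distance with tree path length as ground distance.  Two
equivalent formulations are implemented:

* **Branch sum** (`wuf_branch_sum`): Σ over non-root branches of
  ℓ_b · |P_b − Q_b|, where P_b is the fraction of p's mass in the
  leaves below b.  O(total nodes); used as an oracle.
* **Bottom-up mass propagation** (`emd_unifrac_dense`,
  `emd_unifrac_sparse`): place p − q differences at the leaves and push
  the signed "earth" toward the root, each node contributing
  |unbalanced mass| × (branch length to parent) once all of its
  children have been processed.  The dense variant walks every node;
  the sparse variant seeds per-level dictionaries only with leaves
  whose difference is non-zero and therefore touches only the union of
  their ancestor paths.  Levels are processed deepest-first, which
  handles trees of arbitrary (varying) depth and multifurcations
  without any per-node child counting.

The value reported is the raw (unnormalized) EMD on relative
abundances.  Only this form is a metric in the sense the indexes
require; radius thresholds are configuration on the same scale as the
tree's branch lengths, with 0.1/0.2/0.3/0.4 surfaced in the CLI and
0.3 the default.

Numerical choices: profiles must sum to 1 within 1e-9; residual masses
with magnitude < 1e-12 are treated as balanced and not propagated
(preventing floating-point dust from dragging the traversal to the
root); the root carries no parent branch and never contributes.

Bray-Curtis dissimilarity, used by the coarse search, is computed on
counts — 1 − 2·Σ min(p_i, q_i) / (depth_p + depth_q) — with pairwise
rarefaction available to remove depth bias.  It is bounded in [0, 1]
and is not a metric, which is precisely why the coarse path searches a
fixed representative set instead of an index.

## Preprocessing

* **Relative abundance**: division by depth; support unchanged.
* **16S copy-number correction**: each OTU count divided by its operon
  copy number; OTUs missing from the table default to 1 and are
  reported in a warning.  Correction produces fractional counts.
* **Pairwise (adaptive) rarefaction**: for each compared pair, the
  deeper profile is uniformly subsampled without replacement
  (multivariate hypergeometric) to the shallower depth; the shallower
  profile passes through unchanged.  The random stream is derived from
  the job seed and the *sorted* pair of sample ids, so results do not
  depend on comparison order.  Because correction yields fractional
  counts, rarefaction must precede it; the integer-count precondition
  enforces this ordering.

## Exact search

* **GNAT**: at each node, up to `branching` (default 8) pivots are
  chosen greedily max-min from a seeded candidate sample of 3×branching
  points; remaining points join their nearest pivot's Dirichlet domain;
  the per-pivot-pair [min, max] distance ranges to each subtree are
  exact by construction.  Recursion stops at `leaf_bucket` (default
  16) points.  Range search evaluates all pivots of a visited node
  (recording each true distance) and prunes child j whenever some
  pivot's range to j misses [d(q, pivot) − r, d(q, pivot) + r].
  The cited algorithm descriptions leave these parameters open; the
  defaults here are stated as such.
* **AESA**: the complete pairwise matrix (C(|M|, 2) evaluations) is
  precomputed.  At query time the candidate with the smallest lower
  bound lb(s) = max over evaluated pivots |d(q, p) − d(p, s)| is
  evaluated next, and candidates with lb > radius are discarded
  unevaluated.  Ties break by ascending sample id throughout.
* A brute-force linear scan is retained as the correctness oracle;
  property tests assert hit-set equality for all three on random
  fixtures and radii.

Every search returns the ledger of all true distance evaluations; the
engine reuses these recorded comparisons when assembling the
contextualization matrix, so no distance is ever computed twice.

## Contextualization

Only database samples compared to *every* query can enter the context
set M′ (the complete matrix admits no missing cells); of those, a
sample is kept iff it ranks in the top k (default 20) recorded
distances of at least one query, with ranking restricted to that
common intersection.  ("Top k" could alternatively be read as ranking
over each query's full evaluated set; the intersection reading is used
because it alone guarantees a complete M′×N block.)  The full matrix is
then assembled block-wise — M′×M′ from the precomputed store, M′×N from
the search records, N×N by direct kernel calls — and fed to:

* **PCoA**: classical scaling (double-centering of −D²/2, symmetric
  eigendecomposition).  Axes with negative eigenvalues — the
  non-Euclidean residue UniFrac matrices routinely carry — are dropped
  with a warning; coordinates are ordered by eigenvalue.
* **UPGMA**: average-linkage clustering; the dendrogram is emitted as
  newick with each merge at half its linkage distance (ultrametric
  heights), so two samples at distance d join at height d/2.

## Empirical p-values

The significance of a match at distance d is the fraction of all
database pair distances strictly smaller than d.  A 10,000-bin
histogram of pair distances with its cumulative sum answers this in
O(log bins): the p-value is the cumulative count at the lower edge of
the bin containing d, divided by C(|M|, 2) — conservative by
construction and exact to one bin width.  The last bin edge sits just
above the maximum observed distance so that any larger query distance
maps to p = 1.

## Coarse search representatives

Representatives for Analysis Type II are the medoids of an
average-linkage clustering of the precomputed matrix cut into at most
1000 clusters, after applying the ecosystem filter; a pool still larger
than the cap is down-sampled uniformly with the job seed.  (How the
original system derives representatives from hierarchical clustering is
not fully specified; medoids of a tree cut are this package's choice.)

## Key-index false-negative evaluation

A sample's key is its up-to-5 most abundant phyla in descending order
(ties lexicographic, the "unclassified" bucket losing ties).  For each
distance threshold t, `phyla_index_fn_table` counts pairs closer than t
and, among them, pairs whose keys differ — close pairs a key-based
index would miss.  Percentages are 100·differing/total, rounded half-up
to two decimals, and reported as undefined (not zero) when no pair
falls below the threshold.

## Synthetic data

The generator emulates the statistical structure the search relies on:
high-dimensional, sparse abundance vectors clustered by environment.

* **Trees**: random binary merge order (coalescent-style) with
  exponential branch lengths, rescaled so the mean root-to-leaf depth
  is 0.5.  This calibration puts typical weighted-UniFrac distances
  between unrelated sparse profiles in the upper half of [0, 1] and
  within-ecosystem distances in the 0.05–0.3 band, matching the scale
  the configured radii assume.
* **Profiles**: each ecosystem owns a random leaf subset of size
  sparsity × n_leaves with a Dirichlet(1) center; a sample draws
  θ ~ Dirichlet(center × separation) (separation default 50; smaller
  values create harder, more overlapping ecosystems) and counts
  ~ Multinomial(depth, θ) with depth ~ Poisson(mean_depth, default
  500).  Defaults give mean per-sample support close to
  sparsity × n_leaves.
* Taxonomy comes from clade cuts along each root-to-leaf path; copy
  numbers are uniform integers in 1..10; metadata carries the true
  ecosystem label.

What the fixtures do *not* model: sequencing error and chimeras,
compositional biases of primer/extraction protocols, realistic phylum
structure, or databases at the 10⁴–10⁵-sample scale.  Passing tests
therefore demonstrate algorithmic correctness (exactness of the
indexes, kernel equivalence, pipeline plumbing) and qualitative
behavior (ecosystem recovery, sparse-traversal economy), not
field-realistic effect sizes.  In particular the published
visited-node fraction of ~0.2–0.6% on a ~200,000-node reference
phylogeny shrinks here to ~10–20% simply because desk-scale trees are
shallow; the property that holds at every scale — visited nodes
bounded by the ancestor-path union of differing leaves — is what the
suite asserts.

## Problem sizes in the shipped checks

The test suite and the acceptance script use 1000 random kernel
fixtures on trees of up to 200 leaves, a 500-sample database with 10
held-out queries for index exactness, a 1000-leaf tree for the
sparsity bound, and 2500–3000-distance histograms for p-value
accuracy.  These sizes were chosen to make every check complete in
seconds while leaving the asserted properties scale-independent.

## Known limitations

* Bray-Curtis precomputation for Type II contextualization is done on
  the fly rather than from a second persistent store.
* HDF5-BIOM input is not supported (TSV and BIOM-JSON are); the
  distance store uses a plain HDF5 dense-matrix layout.
* The GNAT is rebuilt per job unless an index file is supplied;
  no incremental updates.
* Query-count limits (10 for GNAT, 100 for AESA) are enforced at the
  CLI and by default programmatically, but `max_queries` can override
  them.
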