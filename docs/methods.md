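# Methods

## Model and procedure

Each of m subjects is described by a square N×N connectivity matrix
A<sub>α</sub> (functional correlation or structural streamline strength;
symmetric, finite). The pipeline treats each brain node as an independent "view" of
the cohort and fuses the views by consensus:

**Nodal distances.** For node i the nodal pattern of subject α is the row
A(i,·)<sub>α</sub>. Two metrics are provided:

- `spearman_one_minus_r`: d = 1 − ρ, ρ the Spearman rank correlation of the
  two patterns. Invariant under any common monotone transform of the
  connectivity values; range [0, 2]; not a metric (no triangle inequality).
- `pearson_sqrt`: d = √(2(1 − r)), r the Pearson correlation. This is the
  Euclidean distance between the standardized patterns, so it satisfies the
  triangle inequality.

By default the self-entry A(i, i) is removed from both patterns before
correlating: it is constant across subjects for correlation matrices
(always 1) and for structural matrices (always 0), contributes no
information, and corrupts rank ties. `keep_diagonal=True` restores it.
Spearman ties use average ranks. Negative correlations are kept (d up to
2); no clipping beyond floating-point guard rails. Constant nodal patterns
make the correlation undefined and raise an error naming subject and node.

**Layer clustering.** Each m×m layer is partitioned by PAM k-medoids:
greedy BUILD initialization plus random restarts (default 20), each
followed by steepest-descent SWAP until no cost-decreasing swap exists, the
lowest-cost restart winning. Swap deltas use the nearest/second-nearest
medoid decomposition, and the inner loops are numba-compiled, so one swap
scan is O(m² + mk). Restart initializations and per-(node, k) sub-seeds
come from a counter-based seed-sequence scheme keyed by (seed, node, k), so
results are independent of execution order. If duplicated points ever empty
a cluster, the partition simply records fewer distinct labels; downstream
only consumes coassignment, which is invariant to relabeling.

**Consensus.** C is the entrywise mean of the binary coassignment matrices
of all (node, k) partitions, every partition carrying equal weight.
Entries are exact multiples of 1/n_partitions; the diagonal is exactly 1.
The default k range is 2..min(21, m−1), fusing structure at twenty
resolutions.

**Null model and communities.** P is the coassignment expected when each
partition's label vector is randomly permuted across subjects. Under this
ensemble P is uniform off-diagonal with value
mean over partitions of Σ<sub>c</sub> n<sub>c</sub>(n<sub>c</sub>−1)/(m(m−1)).
The closed form is the default; a Monte-Carlo permutation mode (default
1000 shuffles) estimates the same quantity and serves as its own check —
the two agree within the usual 1/√n Monte-Carlo error. P's diagonal is set
to 1 so that B = C − P has zero diagonal; self-coassignment is
uninformative and the objective ignores it.

Louvain is applied to B directly as a modularity matrix — greedy node
moving plus graph aggregation, with no internal null subtraction. The
objective is Q = Σ<sub>α≠β</sub> B<sub>αβ</sub> δ(c<sub>α</sub>,c<sub>β</sub>) / Σ<sub>α≠β</sub> C<sub>αβ</sub>;
the normalization is a declared convention (any positive constant leaves
the argmax unchanged). Each of the default 20 runs uses a fresh random node
order and is followed by 8 iterated-local-search refinements (perturb a
random 20% of labels, re-descend, keep on improvement); this removes the
order-independent local optima that pure greedy node moving cannot escape —
on random signed matrices with m ≤ 8 the refined search matches the
exhaustive-enumeration optimum in 100/100 trials, where plain multistart
Louvain managed about 91/100. Ties between runs go to fewer communities,
then the lexicographically smallest label vector, making the result
deterministic given the seed. An all-zero B returns one community with
Q = 0.

## Planted-group benchmark

The generator emulates cohort heterogeneity directly in distance space (no
synthetic connectomes are constructed): m subjects in planted groups,
n_nodes layers of which n_informative carry signal. In an informative
layer each within-group pair draws its distance uniformly from
[0.1, 0.4) and each between-group pair from [0.2, 0.4); uninformative
layers draw every pair from [0.2, 0.4). Defaults: 4 groups of 25, 30
nodes, 10 informative. Variants used by the evaluation: a harder
between-interval [0.15, 0.4) and a 2×50 cohort. Each unordered pair is
sampled once (half-open intervals) and mirrored. Because the model lives
in distance space, the pipeline is entered at the layer-clustering stage.

What the benchmark does not emulate: correlated noise across nodes,
head-motion or scanner artifacts, unequal group sizes, hierarchical or
overlapping group structure, and any realistic connectome topology.
Passing it shows the fusion machinery recovers planted partitions from
weak per-layer signal — not that it handles real fMRI confounds.

A structural property of this benchmark worth knowing: at the default
noise level, the k-medoids cost optimum on the node-averaged distance
matrix does *not* coincide with the planted partition — the cost-optimal
medoid set is measurably cheaper than the truth-aligned one, and the
baseline plateaus near 0.77 mean accuracy no matter how hard the
optimizer works (verified against an independent PAM implementation and
against brute-force medoid enumeration on small instances). The consensus
pipeline, by contrast, recovers the planted groups exactly once k is
averaged over 2..21. The gap between the two is the method's selling
point, and is what the trend tests assert.

## Accuracy statistic

With M = min(number of true groups, number of clusters), the M largest
clusters (ties at equal size going to the smaller label) each contribute
the cardinality of their largest intersection with any single group; the
sum is divided by m. No one-to-one matching is imposed, so several
clusters may claim the same group — a single all-subjects cluster against
4×25 groups scores exactly 0.25. A stricter Hungarian-matched variant
(`matched_accuracy`) is provided for comparison but is not used by the
evaluation harness.

## Downstream analyses

- **Density thresholding**: the ⌈density · m(m−1)/2⌉ largest off-diagonal
  entries (raw signed values by default; `absolute=True` ranks by
  magnitude) keep their weights, the rest are zeroed; ties at the cutoff
  keep lower (row, col) pairs so the retained count is exact. Weights are
  retained rather than binarized — the consensus machinery is built for
  weighted networks.
- **Consensus similarity**: Pearson correlation of upper-triangle entries.
- **Phenotype association**: two communities (or largest-vs-rest when more)
  compared per variable by a two-sided Wilcoxon rank-sum test — exact null
  when both groups have ≤ 25 members and no ties, normal approximation
  with tie correction otherwise — with Bonferroni correction across
  variables, plus the quantiles of a 500-shuffle null of the group-mean
  difference.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated data.
The baseline benchmark averages 50 seeds (k = 4, 20 PAM restarts); the
full-pipeline recovery check averages 20 seeds with k = 2..21 and 5
restarts per layer; the informative-node sweep uses 10 seeds per point and
3 restarts — restart counts chosen so that each configuration's result is
stable seed-to-seed at these problem sizes. Distance layers are validated
to be symmetric within 1e-8 and are symmetrized exactly before use;
consensus-grid and modularity identities are asserted to 1e-9; swap
descent uses a 1e-12 improvement threshold so it terminates on exact
plateaus.

## Limitations

- One consensus round only; no iterated re-clustering of the consensus
  matrix until convergence.
- k-medoids is the only per-layer clusterer; the consensus stage consumes
  arbitrary label vectors, so other clusterers can be fused by
  constructing partitions externally and calling the consensus functions
  directly.
- The Q value depends on the declared normalization; compare Q across runs
  of this package only.
- No missing-value support in connectivity matrices; incomplete phenotype
  cells are allowed and dropped pairwise.
- fMRI/DTI preprocessing (atlas extraction, time-series cleaning) is out
  of scope; inputs are already-extracted connectivity matrices.
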