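# conncluster

Consensus clustering of subjects from their brain connectivity matrices.

Cohorts in connectomics — patients and controls alike — are heterogeneous,
and a single feature vector per subject throws away the structure of the
connectome. `conncluster` groups subjects by fusing, across brain nodes, the
clustering signal carried by each node's connectivity pattern:

1. **Distance layers.** For each node *i*, compare the nodal connectivity
   patterns A(i,·)<sub>α</sub> of every subject pair (α, β) and set
   d<sub>αβ</sub> = 1 − r with *r* their Spearman correlation (or
   d<sub>αβ</sub> = √(2(1 − r)) with *r* Pearson). The N node-wise m×m
   matrices form a multilayer subject-similarity network.
2. **Layer partitions.** Partition each layer with PAM k-medoids, for *k*
   ranging over an interval (default 2..21) to capture structure at several
   resolutions.
3. **Consensus matrix.** C<sub>αβ</sub> = fraction of all (node, k)
   partitions that place α and β in the same cluster.
4. **Communities.** Subtract the permutation-null expected coassignment P
   (uniform off-diagonal, value Σ<sub>c</sub> n<sub>c</sub>(n<sub>c</sub>−1)/(m(m−1))
   averaged over partitions) and maximize modularity
   Q = Σ<sub>α≠β</sub> B<sub>αβ</sub> δ(c<sub>α</sub>, c<sub>β</sub>) / Σ C
   on B = C − P with a Louvain routine that accepts modularity matrices
   directly.

The output is both a partition of subjects into communities and the
consensus matrix itself, a weighted-network representation of cohort
heterogeneity. A planted-group benchmark generator and an evaluation
harness (planted-partition accuracy, density thresholding, consensus
similarity, phenotype association) are included.

## Worked example

Simulate the benchmark — 100 subjects in 4 planted groups of 25, described
by 30 distance layers of which only 10 are informative — then compare the
consensus pipeline against the standard approach (k-medoids with the true
k on the node-averaged distance matrix):

```python
from conncluster import (ToySpec, simulate, consensus_pipeline,
                         baseline_average_kmedoids, accuracy)

dstack, truth = simulate(ToySpec(seed=1))
res = consensus_pipeline(dstack, k_values=range(2, 22), seed=1,
                         restarts=5, louvain_runs=20)
base = baseline_average_kmedoids(dstack, 4, seed=1, restarts=20)
print("communities:", res.communities.n_communities,
      "sizes:", res.communities.community_sizes().tolist())
print("modularity Q: %.4f" % res.communities.modularity_value)
print("consensus accuracy: %.2f" % accuracy(truth, res.communities).accuracy)
print("baseline accuracy:  %.2f" % accuracy(truth, base).accuracy)
```

prints

```
communities: 4 sizes: [25, 25, 25, 25]
modularity Q: 0.1146
consensus accuracy: 1.00
baseline accuracy:  0.79
```

The consensus pipeline recovers the four planted groups exactly — without
being told how many there are — while the average-distance baseline, even
given the true k = 4, misassigns about a fifth of the subjects: the
informative signal that is diluted in the averaged matrix is recovered when
each node's layer is clustered separately and the partitions are fused.

The same stages are available from the shell:

```sh
conncluster toy --preset fig3_4groups --seed 1 --out toy/
conncluster consensus --distances toy/ --k 2:21 --seed 1 --out run/
conncluster evaluate --distances toy/ --communities run/communities.tsv \
    --truth toy/ground_truth.tsv --k 4 --out eval/
```

Real connectome stacks enter through `read_stack` (a directory of
delimited-text matrices, one per subject, or one `.npz` container) and
`run_pipeline`, which prepends the distance-layer construction.

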