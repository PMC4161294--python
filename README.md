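# netripley

Network adaptation of Ripley's K-function for quantifying the association
between gene sets (or continuous gene scores) and molecular networks.

## The problem

High-throughput experiments increasingly produce *networks* — genetic
interaction maps, protein–protein interaction networks, co-expression
networks — rather than ranked gene lists. Classical enrichment methods
(over-representation tests, GSEA) annotate lists; they cannot say whether a
functional gene set is *clustered* on a network, which is the natural
network analogue of enrichment under the guilt-by-association principle:
genes that sit close together on a network tend to share function.
Eyeballing a network layout is not a statistic. This package provides one.

## The statistic

Given an undirected graph with a node-pair distance `d(i, j)` (shortest
path, diffusion-kernel metric, or symmetrised mean first-passage time) and
nonnegative node weights `p_1 … p_n` (binary membership or scores derived
from p-values via `w = −log10 p`), the network K-function is

```
Knet(s) = 2 / (n·p̄²) · Σ_i p_i · Σ_{j≠i} (p_j − p̄₋ᵢ) · 1[d(i,j) ≤ s]
```

where `p̄` is the mean weight and `p̄₋ᵢ` the mean over the other nodes.
The curve starts and ends at zero; if high-weight nodes are mutually close,
weight accumulates at small `s` and the **area under the K-curve (AUK)**
grows. Significance is assessed by permuting the weights over the nodes
(ignoring degree, so the null is exchangeable) and applying a one-sided
Z-test to the observed AUK against the permuted AUKs.

The inner sum alone gives the node-wise curve

```
Knode_i(s) = 2 / (n·p̄) · Σ_{j≠i} (p_j − p̄₋ᵢ) · 1[d(i,j) ≤ s]
```

whose AUK ranks each node by how much high weight surrounds it — a
guilt-by-association prioritisation score satisfying
`Knet(s) = (1/p̄) Σ_i p_i Knode_i(s)`.

Unlike the *compactness score* (mean pairwise hit distance, included here
as a baseline), the K-function sees the global structure of the network:
three mutually adjacent hits in a dense hub are unremarkable, the same
pattern in a sparse region is not, and only the K-function tells them
apart.

## Worked example

Plant a 5-gene cluster on a 100-node scale-free network and test it:

```python
import netripley as nr

net = nr.generate_ba_network(100, 1, seed=7)
nr.write_network(net, "network.tsv")
dist = nr.shortest_path_distances(net)
hits = nr.sample_clustered_hits(net, dist, cutoff=8, n_hits=5, seed=3)
nr.write_gene_sets([nr.GeneSet("CLUSTERED", "planted cluster", hits.members)],
                   "sets.gmt")
```

```
$ netripley knet --network network.tsv --gmt sets.gmt --geneset CLUSTERED \
      --nperm 1000 --seed 1
{
  "observed_auk": 278.30303030303014,
  "z_score": 3.03348707217579,
  "p_value": 0.0012087253442440494,
  "n_perm": 1000,
  "seed": 1,
  "distance_method": "shortest_path",
  "permuted_auk_mean": 0.23498989898982336,
  "permuted_auk_sd": 91.6661366236165,
  "version": "0.1.0"
}
```

The observed AUK (278.3) sits 3.03 permutation standard deviations above
the permuted mean (0.23): the five genes cluster far more tightly than a
random placement, p ≈ 0.0012. The per-gene ranking highlights the
neighbourhood of the planted cluster:

```
$ netripley knode --network network.tsv --gmt sets.gmt --geneset CLUSTERED | head -4
node    score   rank
v92     4.432323232323234       1
v65     4.14949494949495        2
v95     4.14949494949495        3
```

Other subcommands: `compactness` (the baseline statistic), `compare`
(differential gene-set association between two networks), `distances`
(export a distance matrix) and `simulate calibration` / `simulate recovery`
(the planted-cluster benchmark studies). Input formats are plain TSV edge
lists (`node_a`, `node_b`, optional `score`/`distance` columns), GraphML,
GMT gene sets and two-column TSV node weights.

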