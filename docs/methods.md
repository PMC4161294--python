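# Methods

## Model

The package treats a molecular network as an undirected, simple,
node-labelled graph `G = (V, E)` with `n` nodes. Optional per-edge
attributes carry the raw interaction `score` (any sign; larger magnitude =
stronger) and a derived nonnegative `distance` (0 = strongest). Node
weights `p_i ≥ 0` encode the phenotype: binary for gene-set membership,
continuous for significance-derived scores. All matrices and vectors are
aligned to a canonical node order (first appearance in the input), which
the `Network` wrapper owns.

### The K-function

For an evaluation distance `s`,

    Knet(s) = 2/(n·p̄²) · Σ_i p_i · Σ_{j≠i} (p_j − p̄₋ᵢ) · 1[d(i,j) ≤ s]

with `p̄` the mean weight and `p̄₋ᵢ = (Σ_j p_j − p_i)/(n − 1)`. Design
choices embedded in this form, and why:

- **Self-pairs are excluded** and the inner centring uses the
  *leave-one-out* mean. Together these pin both endpoints of the curve to
  zero exactly: at `s = 0` no distinct pair is captured, and at the graph
  diameter `Σ_{j≠i}(p_j − p̄₋ᵢ) = 0` identically. Centring on the global
  mean instead would leave a residual `−(p_i − p̄)` at the diameter and the
  curve would not terminate at zero.
- The `2/(n·p̄²)` normalisation mirrors the unordered-pair counting of the
  planar K-statistic and makes the curve invariant under positive rescaling
  of the weights; the permutation test is invariant to any fixed constant.
- Infinite distances (pairs in different components) never satisfy the
  indicator, so the statistic stays defined on disconnected graphs; the
  evaluation grid ends at the maximum *finite* distance. In practice
  analyses are run on the largest component (`largest_component`).
- Constant weight vectors produce the identically-zero curve; the
  permutation null is then degenerate and the test reports p = 1 with a
  warning rather than failing.

The node-wise curve `Knode_i(s) = 2/(n·p̄) Σ_{j≠i}(p_j − p̄₋ᵢ) 1[d ≤ s]`
carries no outer `p_i` factor, so a node is scored purely by the weight
*around* it; the aggregation identity `Knet = (1/p̄) Σ_i p_i·Knode_i` holds
exactly and is asserted in the tests. Ranks are assigned by descending
AUK with ties broken by node id for determinism.

### Significance

The test statistic is the area under the K-curve (AUK), integrated by the
trapezoidal rule on a shared grid. Any integration rule would do provided
it is identical for observed and permuted curves; the trapezoid is the
simplest consistent choice. The null redistributes the weight vector
uniformly over nodes — degree is deliberately not preserved, keeping the
null exchangeable and the p-values interpretable as "surprise under random
placement". `z = (AUK_obs − mean)/sd` over the permuted AUKs and
`p = 1 − Φ(z)` (upper tail: clustering steepens the curve). The default
permutation count is 1000.

Because the trapezoidal AUK of the step function `s ↦ 1[s ≥ d]` is a fixed
number `T(d)` per node pair, the AUK is a quadratic form in the weight
vector over the matrix `T(d_ij)`. Permuted AUKs are therefore computed
with a single dense matrix product rather than by re-evaluating curves;
this is an algebraic identity (tested as such), not an approximation. The
Z-test on a skewed permutation distribution is mildly anti-conservative:
across pooled null simulations the empirical type-I error at nominal 0.05
is ≈ 0.06. Users needing exact control can read the empirical rank off the
returned permutation sample.

### Evaluation grid

If the distance matrix has at most `n_bins` (default 100) distinct finite
off-diagonal values — always the case for unweighted shortest paths — the
grid is `{0}` plus those values, making the curve exact. Otherwise
`n_bins` equally spaced points from 0 to the maximum finite distance.

## Distance backends

- **Shortest paths** (default): breadth-first search on unweighted graphs,
  Dijkstra with the `distance` edge attribute otherwise (via
  `scipy.sparse.csgraph`). Cross-component pairs are `+inf`.
- **Diffusion kernel**: `K = exp(tL)` with `L` the negative Laplacian
  (`L_ij = w_ij` for edges, `L_ii = −Σ_j w_ij`), computed by symmetric
  eigendecomposition. Rows sum to 1 for every `t` (heat conservation) and
  eigenvalues lie in `(0, 1]`. The kernel is converted to a true metric by
  `d(i,j) = sqrt(K_ii + K_jj − 2K_ij)`, the only conversion that guarantees
  the triangle inequality from a PSD kernel. Diffusion time defaults to
  `t = 1`; it sets the spatial scale of the comparison and is exposed as a
  parameter because no single value suits every network size. Requires a
  connected graph.
- **Mean first-passage time**: for the random walk with transition matrix
  `A_ij = w_ij / Σ_k w_ik`, the analytic solution via the fundamental
  matrix `Z = (I − A + e·πᵀ)⁻¹` gives `m(i→j) = (Z_jj − Z_ij)/π_j`; the
  diagonal of the corresponding matrix expression is the Kac return time
  `1/π_i` and is reported as 0 since the K-statistics exclude self-pairs.
  MFPT is asymmetric; it is symmetrised per pair (default: mean of the two
  directions, `min`/`max` exposed for sensitivity checks).

Dense `n × n` computations (kernel, MFPT) are intended for networks up to
a few thousand nodes; beyond that the shortest-path backend is the
practical choice.

## Transforms

Raw edge scores are mapped to distances so that the strongest interaction
in a network sits at distance 0 and distance is monotone nonincreasing in
score magnitude: `1 − |s|/max|s|` for signed interaction/GI scores,
`1 − r` for profile correlations (shifted so the minimum is exactly 0 when
no perfect correlation is present), `1 − s/max(s)` for positive
log-likelihood scores. P-values become weights through `w = −log10(p)`
with a clamping floor of `1e−300` so that `p = 0` stays finite; `p = 1`
maps to the minimum weight 0. Correlation networks connect profile rows
whose pairwise Pearson `r` exceeds a user threshold; missing entries are
pairwise-complete-deleted with a logged count, and constant rows are
rejected by name because their correlation is undefined.

## Compactness baseline

The compactness of a hit set is the mean graph distance over its unordered
pairs; its permutation test resamples equal-sized hit sets uniformly (the
same null as the K-function test) with a lower-tail Z-test. It is kept as
the contrast baseline: on a clique every hit set has compactness 1, and in
general two hit sets with identical pairwise distances are
indistinguishable to it regardless of how dense their surroundings are —
exactly the blindness the K-function's global accounting removes. The
bundled contrast fixture (a 30-leaf star bridged to a 6-cycle, hit sets of
three star leaves vs. three alternating cycle nodes, both with compactness
2.0) makes this concrete: identical compactness p-values, K-function
p-values two orders of magnitude apart.

## Synthetic benchmarks

The generator produces Barabási–Albert preferential-attachment networks
(attachment parameter 1 by default, i.e. scale-free trees), the common
minimal model of heavy-tailed biological networks.

**Calibration/power study** (500-node networks): a seed node is drawn
uniformly, nodes are ranked by shortest-path distance to it (ties by node
id), and a 5-node hit set is drawn uniformly from the `m` nearest, with
`m ∈ {10, 20, 50, 100, 500}`; `m = 500` is the uniform null. Hits are
binary weights. Under the null the test's p-values are uniform
(Kolmogorov–Smirnov checked); as `m` shrinks the median p-value falls
monotonically, reaching ~1e−7 at `m = 10` with 200 permutations.

**Multi-cluster recovery study** (1000-node networks): 2–4 cluster seeds
are placed by greedy max–min distance, and 10 members per cluster are
drawn without replacement with probability ∝ `exp(−d(seed, v))` (decay
rate 1; clusters are disjoint by construction — later clusters sample from
the remaining nodes). Planted nodes receive significance values from a
truncated normal (mean 0, sd 0.1) on [0, 1]; background nodes draw
uniformly on [0, 1]. Values are p-value-like (small = strong) and pass
through the `−log10` transform before Knode scoring. Recovery is the
fraction of planted nodes ranked in the top `m` (`m` = number planted).
At these settings mean recovery is ≈ 0.32–0.35, an order of magnitude
above the chance level `m/n` = 0.02–0.04, and is flat in the number of
clusters — the per-node statistic does not collapse onto a single cluster.
Note the deliberate difficulty of this design: background values near 0
occur by chance, so planted and background *weights* overlap substantially
and individual planted nodes are not guaranteed to outrank individual
background nodes; the signal is collective.

Every experiment is a pure function of its config and master seed
(per-trial seeds are drawn from a generator seeded by the master), so
trial tables are byte-identical across reruns.

### What the generator does not emulate

Real interaction networks have clustering coefficients, degree
correlations and community structure that preferential-attachment trees
lack; real gene sets overlap heavily and are annotated with biases; real
edge scores carry correlated measurement error. Passing these benchmarks
demonstrates calibration and power of the statistic under a clean planted
model, not performance on any particular experimental map.

## Problem sizes and numerics

The verification experiments use 200 calibration trials, 100 power trials
per cutoff, 50 recovery trials per cluster count and 200 permutations per
test — sizes at which every summary statistic in `scripts/acceptance.py`
is stable to well within the asserted margins. Exact-null agreement is
checked against exhaustive enumeration on all connected graphs with 4–6
nodes plus a seeded sample of 7-node graphs (the 7-node atlas alone has
853 graphs; a sample adds no statistical information at the asserted
Dvoretzky–Kiefer–Wolfowitz bound of 0.027 for 10⁴ draws, fixed a priori
from δ = 1e−6). Kernel PSD violations beyond −1e−10 raise; smaller
negative radicands in the kernel metric are clamped to zero. Weighted
Laplacians and walk matrices use |score| as conductance, since negative
conductances are physically meaningless.

## Known limitations

- The Z-test p-value is a normal-tail approximation; it is mildly
  anti-conservative in the far tail of skewed nulls (see above).
- Dense backends scale as O(n³) time / O(n²) memory.
- The permutation null ignores degree by design; for hit sets strongly
  biased toward hubs, significance conflates clustering with degree bias —
  a property shared with the statistic this implements, documented rather
  than corrected.
- No identifier mapping: gene sets and networks must share a namespace;
  set members absent from the network are dropped with a logged count.
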