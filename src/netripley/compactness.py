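"""Compactness score: the local-clustering baseline statistic.

The compactness of a hit set is the mean graph distance over its unordered
node pairs.  It is a purely local statistic: it looks only at the hits'
mutual distances, not at how many other nodes share that neighbourhood, so
two hit sets with identical pairwise distances are indistinguishable to it
even when one sits in a dense hub (unsurprising) and the other in a sparse
region (surprising).  The Knet permutation test separates such sets; the
compactness permutation test cannot — which is exactly why it is kept here
as a contrast.

Significance is assessed against hit sets resampled uniformly over nodes
(the same exchangeable null as the Knet test), with a lower-tail Z-test:
smaller mean distance means tighter clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .distances import DistanceMatrix
from .network import GeneSet, Network, NetworkError

__all__ = ["CompactnessResult", "compactness_score", "compactness_test"]


@dataclass
class CompactnessResult:
    observed_score: float
    permuted_scores: np.ndarray
    z_score: float
    p_value: float
    n_perm: int
    seed: int


def _hit_indices(net: Network, hits: GeneSet) -> np.ndarray:
    idx = np.array(sorted(net.index_of(m) for m in hits.members if m in net._index))
    if idx.size < 2:
        raise NetworkError("need at least 2 hits mapped to the network")
    return idx


def _mean_pair_distance(dist: np.ndarray, idx: np.ndarray) -> float:
    sub = dist[np.ix_(idx, idx)]
    pairs = sub[np.triu_indices(len(idx), k=1)]
    if not np.all(np.isfinite(pairs)):
        raise NetworkError(
            "hit pair in different components; apply largest_component first"
        )
    return float(pairs.mean())


def compactness_score(dist: DistanceMatrix, net: Network, hits: GeneSet) -> float:
    """Mean distance over unordered pairs of mapped hit nodes."""
    return _mean_pair_distance(dist.values, _hit_indices(net, hits))


def compactness_test(
    dist: DistanceMatrix,
    net: Network,
    hits: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> CompactnessResult:
    """Lower-tail permutation Z-test of hit-set compactness.

    Permuted scores come from hit sets of equal size drawn uniformly over
    all network nodes.  Degenerate nulls (zero variance, e.g. on a clique)
    yield p = 1 with a warning.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    idx = _hit_indices(net, hits)
    observed = _mean_pair_distance(dist.values, idx)
    rng = np.random.default_rng(seed)
    n = dist.n
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        sample = rng.choice(n, size=idx.size, replace=False)
        permuted[k] = _mean_pair_distance(dist.values, np.sort(sample))
    sd = float(np.std(permuted, ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate compactness null (zero variance); p set to 1")
        z, pval = 0.0, 1.0
    else:
        z = (observed - float(np.mean(permuted))) / sd
        pval = float(norm.cdf(z))  # lower tail: small distance = clustering
    return CompactnessResult(observed, permuted, float(z), pval, n_perm, seed)
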