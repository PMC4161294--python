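"""Synthetic benchmarks: planted-cluster networks and recovery experiments.

Two simulation studies define the verification surface for the K-statistics:

**Calibration / power study.**  Scale-free networks (Barabási–Albert
preferential attachment, 500 nodes) are seeded with a hit set of 5 nodes
drawn from the ``m`` nodes nearest a random seed node.  Small ``m`` plants a
tight cluster; ``m`` equal to the network size is the null (uniform hits).
Across trials the Knet permutation p-value should be uniform under the null
and shift toward 0 as ``m`` shrinks.

**Multi-cluster recovery study.**  1000-node networks receive 2–4 planted
clusters: cluster seeds are spread by greedy max–min distance placement,
members are drawn around each seed with probability decaying exponentially
in graph distance, and the planted nodes get near-zero significance values
(truncated normal at 0) while background nodes get uniform values.  The
values are treated as p-value-like (small = strong) and pass through the
−log10 transform before Knode scoring; recovery is the fraction of planted
nodes ranked in the top m, where m is the number of planted nodes.

Every experiment is a pure function of its config and master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .distances import DistanceMatrix, shortest_path_distances
from .kstat import knet_test, knode_scores
from .network import GeneSet, Network, NodeWeights
from .transforms import pvalues_to_weights

__all__ = [
    "CalibrationConfig",
    "RecoveryConfig",
    "generate_ba_network",
    "sample_clustered_hits",
    "assign_multicluster_weights",
    "run_calibration_experiment",
    "run_recovery_experiment",
]

_SEED_CAP = 2**31


@dataclass
class CalibrationConfig:
    """Planted-hit-cluster study on scale-free networks."""

    n_nodes: int = 500
    ba_attachment: int = 1
    distance_cutoffs: tuple[int, ...] = (10, 20, 50, 100, 500)
    n_hits: int = 5
    n_trials: int = 100
    n_perm: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if max(self.distance_cutoffs) > self.n_nodes:
            raise ValueError("distance cutoffs cannot exceed the node count")
        if self.n_hits > min(self.distance_cutoffs):
            raise ValueError("n_hits cannot exceed the smallest cutoff")


@dataclass
class RecoveryConfig:
    """Multi-cluster weight-recovery study."""

    n_nodes: int = 1000
    ba_attachment: int = 1
    n_clusters: int = 3
    nodes_per_cluster: int = 10
    truncnorm_sd: float = 0.1
    interval: tuple[float, float] = (0.0, 1.0)
    decay_rate: float = 1.0
    n_trials: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters * self.nodes_per_cluster >= self.n_nodes:
            raise ValueError("planted nodes must be fewer than network nodes")
        if self.truncnorm_sd <= 0:
            raise ValueError("truncnorm_sd must be > 0")
        lo, hi = self.interval
        if not (0.0 <= lo < hi):
            raise ValueError("interval must satisfy 0 <= lo < hi")


def _node_name(i: int, width: int) -> str:
    return f"v{i:0{width}d}"


def generate_ba_network(n: int, attachment: int = 1, seed: int = 0) -> Network:
    """Connected scale-free network from preferential attachment.

    Node ids are zero-padded (``v000``...) so lexicographic order equals
    construction order.
    """
    if n < 2 or attachment < 1:
        raise ValueError("need n >= 2 and attachment >= 1")
    g = nx.barabasi_albert_graph(n, attachment, seed=int(seed) % _SEED_CAP)
    width = len(str(n - 1))
    g = nx.relabel_nodes(g, {i: _node_name(i, width) for i in g.nodes})
    return Network(g, [_node_name(i, width) for i in range(n)])


def sample_clustered_hits(
    net: Network,
    dist: DistanceMatrix,
    cutoff: int,
    n_hits: int = 5,
    seed: int | np.random.Generator = 0,
) -> GeneSet:
    """Draw a hit set of ``n_hits`` nodes from the ``cutoff`` nodes nearest a
    random seed node.

    The seed node is chosen uniformly; nodes are ranked by distance to it
    (ties broken by node id; the seed node itself, at distance 0, is always
    eligible) and the hit set is drawn uniformly without replacement from
    the ``cutoff`` closest.  ``cutoff == n`` is uniform sampling over the
    whole network.
    """
    n = net.n_nodes
    if not (n_hits <= cutoff <= n):
        raise ValueError("need n_hits <= cutoff <= n_nodes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centre = int(rng.integers(n))
    d = dist.values[centre]
    order = sorted(range(n), key=lambda i: (d[i], net.node_ids[i]))
    sample_set = order[:cutoff]
    chosen = rng.choice(len(sample_set), size=n_hits, replace=False)
    members = frozenset(net.node_ids[sample_set[i]] for i in chosen)
    return GeneSet(f"hits_c{cutoff}", "planted hit set", members)


def _spread_seeds(dist: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    """Greedy max–min placement of k cluster seeds (first seed random)."""
    n = dist.shape[0]
    seeds = [int(rng.integers(n))]
    while len(seeds) < k:
        min_d = np.min(dist[:, seeds], axis=1)
        min_d[seeds] = -np.inf
        seeds.append(int(np.argmax(min_d)))
    return seeds


def assign_multicluster_weights(
    net: Network,
    dist: DistanceMatrix,
    config: RecoveryConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[NodeWeights, np.ndarray]:
    """Plant clusters of significant nodes and return weights + truth labels.

    Cluster members are drawn without replacement around each seed with
    probability proportional to exp(−rate · d(seed, v)); a node can belong
    to at most one cluster (later clusters draw from the remaining nodes).
    Planted nodes receive truncated-normal(0, sd) significance values and
    background nodes uniform values, both on the configured interval; the
    values are converted to weights with the −log10 p-value transform.
    Returns ``(weights, truth)`` with ``truth`` a boolean planted-node mask.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = net.n_nodes
    d = dist.values
    seeds = _spread_seeds(d, config.n_clusters, rng)
    truth = np.zeros(n, dtype=bool)
    for s in seeds:
        available = np.flatnonzero(~truth)
        logits = -config.decay_rate * d[s, available]
        logits -= logits.max()
        probs = np.exp(logits)
        probs /= probs.sum()
        picked = rng.choice(available, size=config.nodes_per_cluster, replace=False, p=probs)
        truth[picked] = True

    lo, hi = config.interval
    raw = np.empty(n)
    n_planted = int(truth.sum())
    a, b = (lo - 0.0) / config.truncnorm_sd, (hi - 0.0) / config.truncnorm_sd
    raw[truth] = truncnorm.rvs(
        a, b, loc=0.0, scale=config.truncnorm_sd, size=n_planted, random_state=rng
    )
    raw[~truth] = rng.uniform(lo, hi, size=n - n_planted)
    weights = pvalues_to_weights(np.clip(raw, None, 1.0))
    return weights, truth


def _trial_seeds(master: int, count: int) -> np.ndarray:
    return np.random.default_rng(master).integers(_SEED_CAP, size=count)


def run_calibration_experiment(config: CalibrationConfig) -> pd.DataFrame:
    """Knet p-values across trials for each planting cutoff.

    One fresh network, hit set and permutation test per (cutoff, trial);
    byte-identical output for a fixed config.
    """
    cutoffs = list(config.distance_cutoffs)
    total = len(cutoffs) * config.n_trials
    seeds = _trial_seeds(config.seed, total)
    rows = []
    k = 0
    for cutoff in cutoffs:
        for trial in range(config.n_trials):
            s = int(seeds[k])
            k += 1
            rng = np.random.default_rng(s)
            net = generate_ba_network(
                config.n_nodes, config.ba_attachment, seed=int(rng.integers(_SEED_CAP))
            )
            dist = shortest_path_distances(net)
            hits = sample_clustered_hits(net, dist, cutoff, config.n_hits, seed=rng)
            w = np.zeros(config.n_nodes)
            for m in hits.members:
                w[net.index_of(m)] = 1.0
            res = knet_test(
                dist,
                NodeWeights(w, kind="binary"),
                n_perm=config.n_perm,
                seed=int(rng.integers(_SEED_CAP)),
            )
            rows.append(
                {
                    "cutoff": cutoff,
                    "trial": trial,
                    "trial_seed": s,
                    "auk": res.observed_auk,
                    "z": res.z_score,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)


def run_recovery_experiment(config: RecoveryConfig) -> pd.DataFrame:
    """Knode top-m recovery of planted nodes across trials."""
    seeds = _trial_seeds(config.seed, config.n_trials)
    rows = []
    for trial in range(config.n_trials):
        s = int(seeds[trial])
        rng = np.random.default_rng(s)
        net = generate_ba_network(
            config.n_nodes, config.ba_attachment, seed=int(rng.integers(_SEED_CAP))
        )
        dist = shortest_path_distances(net)
        weights, truth = assign_multicluster_weights(net, dist, config, seed=rng)
        table = knode_scores(dist, weights, node_ids=net.node_ids)
        m = int(truth.sum())
        top = set(table.sort_values("rank").index[:m])
        truth_ids = {net.node_ids[i] for i in np.flatnonzero(truth)}
        recovery = len(top & truth_ids) / m
        rows.append(
            {
                "n_clusters": config.n_clusters,
                "trial": trial,
                "trial_seed": s,
                "n_planted": m,
                "recovery": recovery,
            }
        )
    return pd.DataFrame(rows)


def config_to_dict(config) -> dict:
    """JSON-serialisable echo of a config (for output provenance headers)."""
    d = asdict(config)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d
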