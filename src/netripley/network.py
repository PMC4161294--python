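"""Graph, node-weight and gene-set containers plus file I/O.

The graph container wraps :class:`networkx.Graph` and pins a canonical node
order (first-appearance order in the input).  Every downstream matrix and
vector — distance matrices, kernels, weight vectors, score tables — is
aligned to that order, so the wrapper is the single source of truth for
node↔index mapping.

Edges may carry two optional numeric attributes:

``score``
    the raw interaction strength as measured (any sign; larger magnitude =
    stronger interaction), and
``distance``
    a nonnegative graph distance derived from the score (0 = strongest
    interaction), as produced by :mod:`netripley.transforms`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("netripley")

__all__ = [
    "Network",
    "NodeWeights",
    "GeneSet",
    "read_network",
    "write_network",
    "read_gene_sets",
    "write_gene_sets",
    "read_node_weights",
    "write_node_weights",
    "gene_set_to_weights",
    "largest_component",
]


class NetworkError(ValueError):
    """Raised for structurally invalid networks or inconsistent inputs."""


@dataclass
class Network:
    """An undirected, simple, node-labelled graph with a fixed node order."""

    graph: nx.Graph
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_ids:
            self.node_ids = list(self.graph.nodes)
        if len(self.node_ids) != self.graph.number_of_nodes() or set(
            self.node_ids
        ) != set(self.graph.nodes):
            raise NetworkError("node_ids must enumerate the graph's nodes exactly")
        self._index = {v: i for i, v in enumerate(self.node_ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def index_of(self, node: str) -> int:
        return self._index[node]

    def has_edge_attribute(self, name: str) -> bool:
        """True if *every* edge carries the named numeric attribute."""
        if self.n_edges == 0:
            return False
        return all(name in d for _, _, d in self.graph.edges(data=True))

    def edge_attribute_matrix(self, name: str, fill: float = 0.0) -> np.ndarray:
        """Dense symmetric matrix of an edge attribute, aligned to node order."""
        n = self.n_nodes
        mat = np.full((n, n), fill, dtype=float)
        for u, v, d in self.graph.edges(data=True):
            i, j = self._index[u], self._index[v]
            mat[i, j] = mat[j, i] = d[name]
        return mat

    def adjacency_matrix(self, weight: str | None = None) -> np.ndarray:
        """Dense symmetric 0/1 (or attribute-weighted) adjacency matrix."""
        n = self.n_nodes
        mat = np.zeros((n, n), dtype=float)
        for u, v, d in self.graph.edges(data=True):
            i, j = self._index[u], self._index[v]
            w = 1.0 if weight is None else float(d[weight])
            mat[i, j] = mat[j, i] = w
        return mat

    def subgraph(self, nodes: Iterable[str]) -> "Network":
        """Induced subgraph; node order inherited from this network."""
        keep = set(nodes)
        order = [v for v in self.node_ids if v in keep]
        return Network(nx.Graph(self.graph.subgraph(order)), order)

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Sequence[str] | None = None,
        scores: Mapping[tuple[str, str], float] | None = None,
        distances: Mapping[tuple[str, str], float] | None = None,
    ) -> "Network":
        """Build a network from an edge list, dropping self-loops and merging
        duplicate edges (keeping the strongest score)."""
        g = nx.Graph()
        order: list[str] = []
        seen: set[str] = set()

        def add_node(v: str) -> None:
            if v not in seen:
                seen.add(v)
                order.append(v)
                g.add_node(v)

        for v in nodes or ():
            add_node(str(v))
        dropped_loops = 0
        for a, b in edges:
            a, b = str(a), str(b)
            add_node(a)
            add_node(b)
            if a == b:
                dropped_loops += 1
                continue
            attrs = {}
            if scores is not None and (a, b) in scores:
                attrs["score"] = float(scores[(a, b)])
            if distances is not None and (a, b) in distances:
                d = float(distances[(a, b)])
                if d < 0 or not np.isfinite(d):
                    raise NetworkError(f"edge distance for ({a}, {b}) must be finite and >= 0")
                attrs["distance"] = d
            if g.has_edge(a, b):
                old = g.edges[a, b]
                if "score" in attrs and "score" in old:
                    if abs(attrs["score"]) > abs(old["score"]):
                        old.update(attrs)
                continue
            g.add_edge(a, b, **attrs)
        if dropped_loops:
            logger.info("dropped %d self-loop(s)", dropped_loops)
        return cls(g, order)


@dataclass
class NodeWeights:
    """Nonnegative per-node weights aligned to a network's node order.

    ``kind`` is ``"binary"`` for gene-set membership indicators and
    ``"continuous"`` for p-value-derived scores.
    """

    values: np.ndarray
    kind: Literal["binary", "continuous"] = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise NetworkError("weights must be a 1-d vector")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise NetworkError("weights must be finite and nonnegative")
        if self.kind == "binary" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise NetworkError("binary weights must be 0/1")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise NetworkError(f"gene set {self.name!r} has no members")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_network(
    path: str | Path, format: Literal["edge_list_tsv", "graphml"] = "edge_list_tsv"
) -> Network:
    """Read a network from an edge-list TSV or a GraphML file.

    The TSV dialect has a mandatory header ``node_a<TAB>node_b`` with optional
    ``score`` and ``distance`` columns.  Self-loops are dropped, duplicate
    edges merged; node order is first-appearance order.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        g = nx.Graph(g)  # undirected, simple
        g.remove_edges_from(nx.selfloop_edges(g))
        return Network(nx.relabel_nodes(g, str), [str(v) for v in g.nodes])
    if format != "edge_list_tsv":
        raise ValueError(f"unknown network format: {format!r}")

    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 2 or cols[0] != "node_a" or cols[1] != "node_b":
            raise NetworkError(f"{path}: expected header starting 'node_a\\tnode_b'")
        extra = cols[2:]
        for c in extra:
            if c not in ("score", "distance"):
                raise NetworkError(f"{path}: unknown column {c!r}")
        edges: list[tuple[str, str]] = []
        scores: dict[tuple[str, str], float] = {}
        distances: dict[tuple[str, str], float] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise NetworkError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            a, b = fields[0], fields[1]
            edges.append((a, b))
            for c, raw in zip(extra, fields[2:]):
                try:
                    val = float(raw)
                except ValueError as exc:
                    raise NetworkError(f"{path}:{lineno}: non-numeric {c} {raw!r}") from exc
                key = (a, b) if a <= b else (b, a)
                target = scores if c == "score" else distances
                if key in target and target[key] != val:
                    raise NetworkError(
                        f"{path}:{lineno}: conflicting {c} for edge ({a}, {b})"
                    )
                target[key] = val
        return Network.from_edges(
            edges,
            scores={k: v for k, v in _rekey(edges, scores).items()},
            distances={k: v for k, v in _rekey(edges, distances).items()},
        )


def _rekey(
    edges: list[tuple[str, str]], attr: dict[tuple[str, str], float]
) -> dict[tuple[str, str], float]:
    out = {}
    for a, b in edges:
        key = (a, b) if a <= b else (b, a)
        if key in attr:
            out[(a, b)] = attr[key]
    return out


def write_network(net: Network, path: str | Path) -> None:
    """Write a network as an edge-list TSV (inverse of :func:`read_network`)."""
    has_score = net.has_edge_attribute("score")
    has_dist = net.has_edge_attribute("distance")
    cols = ["node_a", "node_b"] + (["score"] if has_score else []) + (
        ["distance"] if has_dist else []
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for u, v, d in net.graph.edges(data=True):
            row = [u, v]
            if has_score:
                row.append(repr(float(d["score"])))
            if has_dist:
                row.append(repr(float(d["distance"])))
            fh.write("\t".join(row) + "\n")


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NetworkError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in names:
                raise NetworkError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            names.add(name)
            members = frozenset(m for m in fields[2:] if m)
            sets.append(GeneSet(name, desc, members))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def read_node_weights(
    path: str | Path, column: Literal["weight", "pvalue"] = "weight"
) -> dict[str, float]:
    """Read a two-column TSV of per-node values keyed by node id.

    ``column="pvalue"`` validates values lie in [0, 1]; the caller passes the
    result through :func:`netripley.transforms.pvalues_to_weights`.
    """
    out: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise NetworkError(f"{path}:{lineno}: expected 2 fields")
            node, raw = fields
            if lineno == 1 and raw in ("weight", "pvalue", "value"):
                continue  # optional header
            try:
                val = float(raw)
            except ValueError as exc:
                raise NetworkError(f"{path}:{lineno}: non-numeric value {raw!r}") from exc
            if column == "pvalue" and not (0.0 <= val <= 1.0):
                raise NetworkError(f"{path}:{lineno}: p-value {val} outside [0, 1]")
            if column == "weight" and (val < 0 or not np.isfinite(val)):
                raise NetworkError(f"{path}:{lineno}: weight {val} must be finite, >= 0")
            if node in out:
                raise NetworkError(f"{path}:{lineno}: duplicate node id {node!r}")
            out[node] = val
    return out


def write_node_weights(values: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for node, val in values.items():
            fh.write(f"{node}\t{val!r}\n")


# ---------------------------------------------------------------------------
# Derived objects
# ---------------------------------------------------------------------------

def gene_set_to_weights(gene_set: GeneSet, net: Network) -> tuple[NodeWeights, int]:
    """Binary membership weights for a gene set on a network.

    Returns ``(weights, n_absent)`` where ``n_absent`` counts set members not
    present in the network (excluded, logged).  Raises if no member maps.
    """
    if net.n_nodes == 0:
        raise NetworkError("network is empty")
    values = np.zeros(net.n_nodes)
    present = 0
    for m in gene_set.members:
        idx = net._index.get(m)
        if idx is not None:
            values[idx] = 1.0
            present += 1
    if present == 0:
        raise NetworkError(
            f"gene set {gene_set.name!r} shares no members with the network"
        )
    n_absent = len(gene_set.members) - present
    if n_absent:
        logger.info(
            "gene set %s: %d member(s) absent from the network", gene_set.name, n_absent
        )
    return NodeWeights(values, kind="binary"), n_absent


def largest_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Ties between equal-sized components are broken toward the component
    containing the lexicographically smallest node id.
    """
    if net.n_nodes == 0:
        raise NetworkError("network is empty")
    comps = list(nx.connected_components(net.graph))
    maxlen = max(len(c) for c in comps)
    candidates = [c for c in comps if len(c) == maxlen]
    best = min(candidates, key=lambda c: min(c))
    removed = net.n_nodes - len(best)
    if removed:
        logger.info("largest_component: removed %d node(s)", removed)
    return net.subgraph(best)
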