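"""Node-pair distance backends: shortest paths, diffusion kernel, MFPT.

All backends return a :class:`DistanceMatrix` aligned to the network's node
order.  Shortest paths tolerate disconnected graphs (cross-component pairs
are +inf and never satisfy the K-function indicator); the kernel and
mean-first-passage-time backends require a connected graph.

The diffusion kernel is the matrix exponential of t times the negative
graph Laplacian, K = exp(tL) with L_ij the edge weight (1 if unweighted)
for neighbours and L_ii = −(weighted) degree.  Because L has zero row sums,
K is a stochastic matrix for every t: heat placed on a node spreads across
the graph but is conserved.  The kernel-induced metric
d(i, j) = sqrt(K_ii + K_jj − 2 K_ij) turns the kernel into a true distance.

Mean first-passage time m(i→j) — the expected number of steps for a random
walk started at i to first reach j — is computed from the fundamental
matrix Z = (I − A + e·piᵀ)⁻¹ of the walk's Markov chain as
M = (I − Z + E·Z_dg)·D, where A is the transition matrix, pi its stationary
distribution, E the all-ones matrix, Z_dg the diagonal of Z, and D the
diagonal matrix with D_jj = 1/pi_j.  The diagonal of that expression is the
expected return time 1/pi_i (Kac's identity); it is reported as 0 since the
K-statistics exclude self-pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .network import Network, NetworkError

__all__ = [
    "DistanceMatrix",
    "KernelMatrix",
    "MfptMatrix",
    "shortest_path_distances",
    "diffusion_kernel",
    "kernel_to_distances",
    "mfpt",
    "stationary_distribution",
    "symmetrize_mfpt",
    "distance_grid",
]


@dataclass
class DistanceMatrix:
    """Symmetric n×n node-pair distances with zero diagonal.

    Entries are +inf exactly for node pairs in different components.
    """

    values: np.ndarray
    method: Literal["shortest_path", "diffusion", "mfpt"]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        with np.errstate(invalid="ignore"):
            if np.any(v < 0):
                raise ValueError("distances must be nonnegative")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def max_finite(self) -> float:
        off = self.values[~np.eye(self.n, dtype=bool)]
        finite = off[np.isfinite(off)]
        if finite.size == 0:
            raise ValueError("no finite off-diagonal distances")
        return float(finite.max())


@dataclass
class KernelMatrix:
    """Diffusion kernel exp(tL): symmetric, PSD, rows sum to 1."""

    values: np.ndarray
    t: float

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class MfptMatrix:
    """Mean first-passage times m(i→j); asymmetric in general, zero diagonal."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------

def shortest_path_distances(net: Network, use_edge_distance: bool = False) -> DistanceMatrix:
    """All-pairs shortest-path distances.

    Unweighted graphs use breadth-first search (distance = edge count);
    with ``use_edge_distance`` the ``distance`` edge attribute is summed
    along paths and Dijkstra's algorithm is used.  Cross-component pairs
    get +inf.
    """
    n = net.n_nodes
    if n == 0:
        raise NetworkError("network is empty")
    rows, cols, data = [], [], []
    for u, v, d in net.graph.edges(data=True):
        i, j = net.index_of(u), net.index_of(v)
        if use_edge_distance:
            if "distance" not in d:
                raise NetworkError("use_edge_distance requires a distance on every edge")
            w = float(d["distance"])
            if w < 0:
                raise NetworkError("negative edge distance")
        else:
            w = 1.0
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
    adj = scipy.sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    if use_edge_distance:
        dist = _csgraph_shortest_path(adj, method="D", directed=False)
    else:
        dist = _csgraph_shortest_path(adj, method="D", directed=False, unweighted=True)
    np.fill_diagonal(dist, 0.0)
    dist = np.minimum(dist, dist.T)  # symmetrize away float round-off
    return DistanceMatrix(dist, "shortest_path")


# ---------------------------------------------------------------------------
# Diffusion kernel
# ---------------------------------------------------------------------------

def _negative_laplacian(net: Network, use_edge_score: bool) -> np.ndarray:
    weight = "score" if use_edge_score else None
    if use_edge_score and not net.has_edge_attribute("score"):
        raise NetworkError("weighted Laplacian requires a score on every edge")
    adj = net.adjacency_matrix(weight=weight)
    if use_edge_score:
        adj = np.abs(adj)  # conductances must be nonnegative
    lap = adj.copy()
    np.fill_diagonal(lap, -adj.sum(axis=1))
    return lap


def diffusion_kernel(net: Network, t: float = 1.0, use_edge_score: bool = False) -> KernelMatrix:
    """Diffusion kernel K = exp(tL) via symmetric eigendecomposition."""
    if t <= 0:
        raise ValueError("diffusion time t must be > 0")
    if not net.is_connected():
        raise NetworkError(
            "diffusion kernel requires a connected network; apply largest_component first"
        )
    lap = _negative_laplacian(net, use_edge_score)
    eigval, eigvec = scipy.linalg.eigh(lap)
    kern = (eigvec * np.exp(t * eigval)) @ eigvec.T
    kern = (kern + kern.T) / 2.0
    return KernelMatrix(kern, t=float(t))


def kernel_to_distances(kernel: KernelMatrix) -> DistanceMatrix:
    """Kernel-induced metric d(i,j) = sqrt(K_ii + K_jj − 2 K_ij)."""
    k = kernel.values
    diag = np.diag(k)
    sq = diag[:, None] + diag[None, :] - 2.0 * k
    if sq.min() < -1e-10:
        raise ValueError(f"kernel is not PSD: squared distance {sq.min():.3e}")
    sq = np.clip(sq, 0.0, None)
    dist = np.sqrt(sq)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix((dist + dist.T) / 2.0, "diffusion")


# ---------------------------------------------------------------------------
# Mean first-passage time
# ---------------------------------------------------------------------------

def _transition_matrix(net: Network, use_edge_score: bool) -> tuple[np.ndarray, np.ndarray]:
    weight = "score" if use_edge_score else None
    if use_edge_score and not net.has_edge_attribute("score"):
        raise NetworkError("weighted walk requires a score on every edge")
    adj = net.adjacency_matrix(weight=weight)
    if use_edge_score:
        adj = np.abs(adj)
    strength = adj.sum(axis=1)
    if np.any(strength == 0):
        raise NetworkError("isolated node: random walk undefined")
    trans = adj / strength[:, None]
    pi = strength / strength.sum()
    return trans, pi


def mfpt(net: Network, use_edge_score: bool = False) -> MfptMatrix:
    """Analytic mean first-passage times of the random walk on the network."""
    if not net.is_connected():
        raise NetworkError(
            "MFPT requires a connected network; apply largest_component first"
        )
    trans, pi = _transition_matrix(net, use_edge_score)
    n = net.n_nodes
    fundamental = np.linalg.inv(np.eye(n) - trans + np.outer(np.ones(n), pi))
    z_diag = np.diag(fundamental)
    # m(i->j) = (Z_jj - Z_ij) / pi_j; diagonal (return time 1/pi_i) zeroed
    m = (z_diag[None, :] - fundamental) / pi[None, :]
    np.fill_diagonal(m, 0.0)
    return MfptMatrix(m)


def stationary_distribution(net: Network, use_edge_score: bool = False) -> np.ndarray:
    """Stationary distribution pi of the random walk (degree / total degree)."""
    _, pi = _transition_matrix(net, use_edge_score)
    return pi


def symmetrize_mfpt(m: MfptMatrix, mode: Literal["mean", "min", "max"] = "mean") -> DistanceMatrix:
    """One distance per unordered pair from the asymmetric passage times."""
    v = m.values
    if mode == "mean":
        sym = (v + v.T) / 2.0
    elif mode == "min":
        sym = np.minimum(v, v.T)
    elif mode == "max":
        sym = np.maximum(v, v.T)
    else:
        raise ValueError(f"unknown symmetrization mode {mode!r}")
    np.fill_diagonal(sym, 0.0)
    return DistanceMatrix(sym, "mfpt")


# ---------------------------------------------------------------------------
# Evaluation grid
# ---------------------------------------------------------------------------

def distance_grid(dist: DistanceMatrix, n_bins: int = 100) -> np.ndarray:
    """Ordered evaluation distances from 0 to the graph diameter.

    If the matrix has at most ``n_bins`` distinct finite off-diagonal values
    (the typical unweighted case) the grid is {0} plus those values; otherwise
    ``n_bins`` equally spaced points.  Always starts at 0 and ends at the
    maximum finite distance.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    off = dist.values[~np.eye(dist.n, dtype=bool)]
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        raise ValueError("all off-diagonal distances are infinite")
    distinct = np.unique(finite)
    if distinct.size <= n_bins:
        grid = np.unique(np.concatenate(([0.0], distinct)))
    else:
        grid = np.linspace(0.0, float(distinct[-1]), n_bins)
        grid[0] = 0.0
    return grid
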