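"""Score-to-distance, p-value-to-weight and correlation-network transforms.

Graph-distance backends expect *small* edge distances for *strong*
interactions, with the strongest interaction in a network sitting at
distance 0.  Experimentally derived networks instead carry raw scores
(genetic-interaction epsilon scores, profile correlations, modified-T
interaction scores, log-likelihood scores) where *large magnitude* means
strong.  The per-scheme maps here flip that orientation:

========================  =============================================
scheme                    edge distance
========================  =============================================
``gi_score``              ``1 − |s| / max|s|``
``interaction_score``     ``1 − |s| / max|s|``
``correlation``           ``1 − r`` (then shifted so the minimum is 0)
``log_likelihood``        ``1 − s / max(s)`` (scores must be positive)
========================  =============================================

Each map is monotone nonincreasing in score magnitude and lands in [0, 1];
the strongest edge always maps to distance exactly 0 (for the correlation
scheme this is enforced by subtracting the minimum distance, since a
network without a perfect r = 1 edge would otherwise never touch 0).

P-values are converted to node weights by ``w = −log10(p)``, clamped below
at a configurable floor so that w stays finite.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .network import Network, NetworkError, NodeWeights

logger = logging.getLogger("netripley")

__all__ = [
    "scores_to_distances",
    "pvalues_to_weights",
    "build_correlation_network",
    "read_profile_matrix",
]

_SCHEMES = ("gi_score", "correlation", "interaction_score", "log_likelihood")

P_FLOOR = 1e-300


def scores_to_distances(net: Network, scheme: str) -> Network:
    """Fill ``edge_distance`` from ``edge_score`` under the given scheme.

    Modifies edge attributes in place and returns the same network for
    chaining.  Raises if any edge lacks a score or the scores fall outside
    the scheme's domain.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {_SCHEMES}")
    if net.n_edges == 0:
        return net
    if not net.has_edge_attribute("score"):
        raise NetworkError("scores_to_distances: every edge must carry a score")

    edges = list(net.graph.edges(data=True))
    scores = np.array([d["score"] for _, _, d in edges], dtype=float)
    if not np.all(np.isfinite(scores)):
        raise NetworkError("scores must be finite")

    if scheme in ("gi_score", "interaction_score"):
        mags = np.abs(scores)
        top = mags.max()
        if top == 0:
            raise NetworkError("all scores are zero; distances undefined")
        dist = 1.0 - mags / top
    elif scheme == "correlation":
        if np.any(scores < -1.0) or np.any(scores > 1.0):
            raise NetworkError("correlation scores must lie in [-1, 1]")
        dist = 1.0 - scores
        dist = dist - dist.min()  # strongest edge pinned to distance 0
        if dist.max() > 1.0:
            dist = dist / dist.max()
    else:  # log_likelihood
        if np.any(scores <= 0):
            raise NetworkError("log-likelihood scheme requires positive scores")
        dist = 1.0 - scores / scores.max()

    for (u, v, d), x in zip(edges, dist):
        d["distance"] = float(x)
    return net


def pvalues_to_weights(
    p: np.ndarray, floor: float | None = P_FLOOR
) -> NodeWeights:
    """Convert p-values to node weights via ``w = −log10(p)``.

    Smaller p ⇒ larger weight; p = 1 maps to the minimum weight 0.  Values
    below ``floor`` are clamped before the transform so weights stay finite;
    pass ``floor=None`` to disable clamping (p = 0 then raises).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p > 1.0):
        raise ValueError("p-values must be <= 1")
    if floor is not None:
        p = np.maximum(p, floor)
    if np.any(p <= 0.0):
        raise ValueError("p-values must be > 0 (enable clamping for p = 0)")
    return NodeWeights(-np.log10(p), kind="continuous")


def read_profile_matrix(path) -> pd.DataFrame:
    """Read an interaction-profile matrix from TSV (row label + header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise NetworkError("profile matrix has duplicate row labels")
    return df


def build_correlation_network(profiles: pd.DataFrame, threshold: float) -> Network:
    """Connect genes whose interaction profiles correlate above a threshold.

    One node per profile row; an edge joins each unordered row pair whose
    Pearson r exceeds ``threshold``, carrying ``score = r`` and the
    correlation-scheme edge distance.  Missing entries are dropped pairwise
    (with a logged count); constant rows are rejected by name.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if profiles.shape[0] < 2:
        raise NetworkError("need at least 2 profile rows")
    if profiles.shape[1] < 2:
        raise NetworkError("need at least 2 profile columns")
    values = profiles.to_numpy(dtype=float)
    labels = [str(x) for x in profiles.index]
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.info("profile matrix: %d missing entries, pairwise-deleted", n_missing)
    for lab, row in zip(labels, values):
        finite = row[np.isfinite(row)]
        if finite.size < 2 or np.all(finite == finite[0]):
            raise NetworkError(f"profile row {lab!r} is constant; correlation undefined")

    # pairwise-complete Pearson correlation
    corr = pd.DataFrame(values.T, columns=labels).corr(min_periods=2).to_numpy()
    n = len(labels)
    edges: list[tuple[str, str]] = []
    scores: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            r = corr[i, j]
            if np.isfinite(r) and r > threshold:
                edges.append((labels[i], labels[j]))
                scores[(labels[i], labels[j])] = float(r)
    net = Network.from_edges(edges, nodes=labels, scores=scores)
    if net.n_edges:
        scores_to_distances(net, "correlation")
    return net
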