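"""Degree, path-length and clustering metrics on binarized connectomes.

All functions take a boolean adjacency matrix (row = presynaptic) as
produced by :func:`nervering.core.binarize`.  Clustering follows the
undirected convention used for neural wiring diagrams:

    CC(u) = 2 T(u) / (deg(u) (deg(u) - 1))

where deg(u) counts edges touching u regardless of direction (a reciprocal
pair counts once) and T(u) counts neighbor pairs of u that are themselves
connected in either direction.  Nodes with deg(u) < 2 cannot form a
triangle and are excluded (reported as NaN).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import NEURON_TYPES, Roster, StageEnsemble
from .errors import ValidationError


def _as_bool(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValidationError(f"adjacency must be square, got {adj.shape}")
    return adj.astype(bool)


def degrees(adj: np.ndarray, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Out-degree (postsynaptic partner count) and in-degree per node."""
    adj = _as_bool(adj)
    out = adj.sum(axis=1).astype(int)
    inn = adj.sum(axis=0).astype(int)
    index = list(names) if names is not None else list(range(adj.shape[0]))
    return pd.DataFrame({"out_degree": out, "in_degree": inn}, index=index)


def typed_out_degree(
    adj: np.ndarray,
    types: Sequence[str],
    pre_type: str,
    post_type: str,
) -> np.ndarray:
    """Out-degree restricted to one (pre type -> post type) connection class.

    Only sources of ``pre_type`` receive nonzero counts; targets are limited
    to neurons of ``post_type``.
    """
    adj = _as_bool(adj)
    types = np.asarray(types, dtype=object)
    if types.shape[0] != adj.shape[0]:
        raise ValidationError("type map length does not match adjacency")
    for t in (pre_type, post_type):
        if t not in NEURON_TYPES:
            raise ValidationError(f"unknown neuron type {t!r}")
    src = types == pre_type
    dst = types == post_type
    counts = np.zeros(adj.shape[0], dtype=int)
    counts[src] = adj[np.ix_(src, dst)].sum(axis=1)
    return counts


def active_in_any(ensemble: StageEnsemble, weight_floor: float = 0.0) -> np.ndarray:
    """Mask of neurons with at least one connection in at least one stage.

    Used as the cross-ensemble exclusion filter for typed-degree
    comparisons: neurons silent in every dataset are neglected.
    """
    n = len(ensemble.roster)
    mask = np.zeros(n, dtype=bool)
    for stage in ensemble.stages:
        adj = ensemble[stage].binarize(weight_floor)
        mask |= adj.any(axis=1) | adj.any(axis=0)
    return mask


def mean_path_length(adj: np.ndarray, u: int) -> float:
    """Mean directed shortest-path length from ``u`` to its reachable set.

    Paths use unit edge costs; ``u`` itself is excluded.  Returns NaN when
    ``u`` reaches no other node (such sources are excluded from population
    statistics).
    """
    adj = _as_bool(adj)
    G = nx.from_numpy_array(adj, create_using=nx.DiGraph)
    lengths = nx.single_source_shortest_path_length(G, u)
    dists = [d for v, d in lengths.items() if v != u]
    if not dists:
        return float("nan")
    return float(np.mean(dists))


def undirected_degree(adj: np.ndarray) -> np.ndarray:
    """deg(u): edges touching u in the simple underlying undirected graph."""
    U = _as_bool(adj)
    U = U | U.T
    np.fill_diagonal(U, False)
    return U.sum(axis=1).astype(int)


def clustering_coefficient(adj: np.ndarray, u: int | None = None):
    """CC(u) on the underlying undirected graph; NaN where deg(u) < 2.

    With ``u=None`` returns the full per-node array.
    """
    U = _as_bool(adj)
    U = (U | U.T).astype(np.int64)
    np.fill_diagonal(U, 0)
    deg = U.sum(axis=1)
    # T(u) = number of connected neighbor pairs = (U^3)_{uu} / 2
    tri = np.diag(U @ U @ U) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = 2.0 * tri / (deg * (deg - 1.0))
    cc = np.where(deg >= 2, cc, np.nan)
    if u is not None:
        return float(cc[u])
    return cc


def degree_distribution(adj: np.ndarray, kind: str = "out") -> np.ndarray:
    """Exact histogram of degree values; index k holds the node count at k."""
    adj = _as_bool(adj)
    if kind == "out":
        deg = adj.sum(axis=1)
    elif kind == "in":
        deg = adj.sum(axis=0)
    elif kind == "undirected":
        deg = undirected_degree(adj)
    else:
        raise ValidationError(f"unknown degree kind {kind!r}")
    return np.bincount(deg.astype(int))


def survival_slope(hist: np.ndarray) -> float:
    """Slope of log survival P(deg > k) vs k, by least squares.

    For a geometric degree distribution with success probability p the
    survival function is (1-p)^k so the slope estimates log(1-p).
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total == 0:
        raise ValidationError("empty histogram")
    surv = 1.0 - np.cumsum(hist) / total
    ks = np.arange(len(surv))
    # the extreme tail (fewer than 5 nodes surviving) is too noisy to fit
    keep = surv * total >= 5
    ks, surv = ks[keep], surv[keep]
    if len(ks) < 2:
        raise ValidationError("degenerate distribution, cannot fit slope")
    slope = np.polyfit(ks, np.log(surv), 1)[0]
    return float(slope)
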