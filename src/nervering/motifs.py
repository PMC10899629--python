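"""Directed triad census and triangular-motif enrichment against ER nulls.

Every unordered triple of nodes induces one of 16 directed-graph
isomorphism classes (the classic triad census, named by their
mutual/asymmetric/null dyad counts: 003, 012, 102, 021D, 021U, 021C, 111D,
111U, 030T, 030C, 201, 120D, 120U, 120C, 210, 300).  The *triangular*
classes are the seven with no null dyad — every pair of the three nodes is
joined by at least one directed edge — and the triangular proportion of a
network is the fraction of all C(n,3) triples falling in those classes.

The null model is the directed Erdős–Rényi graph matched on node count and
connection probability p = |E| / (n (n-1)); under it each unordered pair is
connected with probability q = 1 - (1-p)^2 independently, so the expected
triangular proportion is q^3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

TRIAD_NAMES = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)

#: classes whose underlying undirected graph is a 3-clique (no null dyad)
TRIANGLE_CLASSES = frozenset({"030T", "030C", "120D", "120U", "120C", "210", "300"})


def _classify_code(code: int) -> str:
    """Name the triad class of a 6-bit edge code.

    Bit order: (0->1, 1->0, 0->2, 2->0, 1->2, 2->1).
    """
    e = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
    edges = {e[b] for b in range(6) if code >> b & 1}
    pairs = [(0, 1), (0, 2), (1, 2)]
    mutual = [p for p in pairs if (p in edges and p[::-1] in edges)]
    asym = [p for p in pairs if ((p in edges) != (p[::-1] in edges))]
    m, a = len(mutual), len(asym)
    n = 3 - m - a
    base = f"{m}{a}{n}"
    if base not in {"021", "111", "030", "120"}:
        return base
    outdeg = {v: sum(1 for (s, _) in edges if s == v) for v in range(3)}
    indeg = {v: sum(1 for (_, t) in edges if t == v) for v in range(3)}
    if base == "021":
        if any(outdeg[v] == 2 for v in range(3)):
            return "021D"  # divergent: one source feeds both others
        if any(indeg[v] == 2 for v in range(3)):
            return "021U"  # convergent: both feed one target
        return "021C"  # chain
    if base == "030":
        cyclic = all(outdeg[v] == 1 and indeg[v] == 1 for v in range(3))
        return "030C" if cyclic else "030T"
    # locate the node outside the mutual dyad
    in_dyad = set(mutual[0])
    third = ({0, 1, 2} - in_dyad).pop()
    to_dyad = sum(
        1 for (s, t) in edges if s == third and t in in_dyad and (t, s) not in edges
    )
    from_dyad = sum(
        1 for (s, t) in edges if t == third and s in in_dyad and (t, s) not in edges
    )
    if base == "111":
        return "111D" if to_dyad == 1 else "111U"
    # base == "120": two asymmetric edges between third and the dyad
    if to_dyad == 2:
        return "120D"
    if from_dyad == 2:
        return "120U"
    return "120C"


#: lookup: 6-bit labeled-edge code -> triad class index into TRIAD_NAMES
TRIAD_LOOKUP = np.array(
    [TRIAD_NAMES.index(_classify_code(c)) for c in range(64)], dtype=np.int8
)

#: boolean mask over the 16 classes marking the triangular ones
TRIANGLE_MASK = np.array([name in TRIANGLE_CLASSES for name in TRIAD_NAMES])


@dataclass
class MotifCensus:
    """Counts over the 16 triad classes for one (sub)network."""

    counts: np.ndarray  # length 16, aligned with TRIAD_NAMES
    n: int  # number of nodes in the analyzed (sub)network

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, int]:
        return {name: int(c) for name, c in zip(TRIAD_NAMES, self.counts)}


def triad_class(adj3: np.ndarray) -> str:
    """Triad class name of a 3-node directed adjacency matrix."""
    adj3 = np.asarray(adj3, dtype=bool)
    if adj3.shape != (3, 3):
        raise ValidationError(f"expected a 3x3 adjacency, got {adj3.shape}")
    code = (
        (adj3[0, 1] << 0) | (adj3[1, 0] << 1) | (adj3[0, 2] << 2)
        | (adj3[2, 0] << 3) | (adj3[1, 2] << 4) | (adj3[2, 1] << 5)
    )
    return TRIAD_NAMES[TRIAD_LOOKUP[int(code)]]


def triad_census(adj: np.ndarray, nodes=None) -> MotifCensus:
    """Full census over all C(n,3) node triples of a binarized network."""
    adj = np.asarray(adj, dtype=bool)
    if nodes is not None:
        nodes = np.asarray(nodes)
        adj = adj[np.ix_(nodes, nodes)]
    n = adj.shape[0]
    counts = np.zeros(16, dtype=np.int64)
    if n < 3:
        return MotifCensus(counts, n)
    triples = np.array(list(itertools.combinations(range(n), 3)))
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    code = (
        adj[i, j].astype(np.int32)
        | adj[j, i] << 1
        | adj[i, k] << 2
        | adj[k, i] << 3
        | adj[j, k] << 4
        | adj[k, j] << 5
    )
    counts = np.bincount(TRIAD_LOOKUP[code], minlength=16).astype(np.int64)
    return MotifCensus(counts, n)


def triangular_proportion(census: MotifCensus, n_total: int | None = None) -> float:
    """Fraction of triples whose three nodes are all pairwise connected.

    The default denominator is the census total C(n,3) of the analyzed
    (sub)network; pass ``n_total`` (e.g. 180) to instead divide by the
    whole-network triple count.
    """
    if census.total == 0:
        raise ValidationError("empty census")
    tri = int(census.counts[TRIANGLE_MASK].sum())
    if n_total is not None:
        denom = n_total * (n_total - 1) * (n_total - 2) // 6
    else:
        denom = census.total
    return tri / denom


def _triangle_count(adj: np.ndarray) -> int:
    U = (adj | adj.T).astype(np.int64)
    np.fill_diagonal(U, 0)
    return int(np.trace(U @ U @ U) // 6)


def observed_triangular_proportion(adj: np.ndarray) -> float:
    """Triangular proportion straight from a binarized adjacency."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 nodes")
    return _triangle_count(adj) / (n * (n - 1) * (n - 2) / 6)


def edge_probability(adj: np.ndarray) -> float:
    """Connection probability |E| / (n (n-1)) of a directed network."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    adj = adj.copy()
    np.fill_diagonal(adj, False)
    return float(adj.sum() / (n * (n - 1)))


@dataclass
class NullDistribution:
    """Triangular proportions of matched directed ER random networks."""

    values: np.ndarray
    n: int
    p: float
    seed: int | None

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.values, q))

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def er_null(
    n: int, p: float, reps: int = 1000, seed: int | None = None
) -> NullDistribution:
    """Triangular proportion distribution over directed ER graphs.

    Each ordered pair (no self-loops) is an edge independently with
    probability ``p``; the expected proportion is (1-(1-p)^2)^3.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"edge probability {p} outside [0, 1]")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    denom = n * (n - 1) * (n - 2) / 6
    vals = np.empty(reps)
    for r in range(reps):
        adj = rng.random((n, n)) < p
        np.fill_diagonal(adj, False)
        vals[r] = _triangle_count(adj) / denom
    return NullDistribution(vals, n, p, seed)


def matched_er_null(
    adj: np.ndarray, reps: int = 1000, seed: int | None = None
) -> NullDistribution:
    """ER null matched on the observed node count and edge probability."""
    adj = np.asarray(adj, dtype=bool)
    return er_null(adj.shape[0], edge_probability(adj), reps=reps, seed=seed)
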