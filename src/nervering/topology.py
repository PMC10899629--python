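"""Network vulnerability, LR-collapsed module detection, and hub detection.

Vulnerability removes edges one at a time in a uniformly random order and
tracks the number of weakly connected components and the size of the
largest one after each removal, averaged over repetitions.  Internally the
curve is computed by *adding* the edges back in reverse order with a
union-find structure, which gives the exact same per-step values in
O(E alpha(n)) per repetition.

Module detection merges left-right homolog pairs (180 neurons -> 97
groups), then runs Clauset–Newman–Moore greedy modularity maximization on
the undirected projection; single-neuron modules are dropped from the
report.  Hub neurons are those whose out-degree strictly exceeds the mean
maximum out-degree of matched directed ER random networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, Neuron, Roster
from .errors import ValidationError


@dataclass
class VulnerabilityCurve:
    """Mean component count / largest-component size per removal step."""

    n_components: np.ndarray  # length E+1; index = edges removed so far
    largest_size: np.ndarray
    reps: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edges_removed": np.arange(len(self.n_components)),
                "n_components": self.n_components,
                "largest_component": self.largest_size,
            }
        )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n
        self.n_components = n
        self.max_size = 1 if n else 0

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.max_size = max(self.max_size, self.size[ra])
        self.n_components -= 1


def vulnerability(
    adj: np.ndarray, reps: int = 100, seed: int | None = None
) -> VulnerabilityCurve:
    """Random sequential edge-removal curve, averaged over ``reps`` orders.

    Directed edges are removed; connectivity is assessed on the weak
    (direction-agnostic) projection over all n nodes.  Step 0 is the intact
    network and step E the edgeless one (n singleton components).
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    edges = np.argwhere(adj)
    E = len(edges)
    rng = np.random.default_rng(seed)
    comp_acc = np.zeros(E + 1)
    size_acc = np.zeros(E + 1)
    for _ in range(reps):
        order = rng.permutation(E)
        # removal order `order`; add back in reverse and record states
        uf = _UnionFind(n)
        comps = np.empty(E + 1)
        sizes = np.empty(E + 1)
        comps[E] = uf.n_components
        sizes[E] = uf.max_size
        for step in range(E - 1, -1, -1):
            u, v = edges[order[step]]
            uf.union(int(u), int(v))
            comps[step] = uf.n_components
            sizes[step] = uf.max_size
        comp_acc += comps
        size_acc += sizes
    return VulnerabilityCurve(comp_acc / reps, size_acc / reps, reps, seed)


def collapse_lr(
    matrix: ConnectivityMatrix,
    pair_map: dict[str, list[str]] | None = None,
) -> ConnectivityMatrix:
    """Merge left-right homolog pairs by summing their weights.

    ``pair_map`` maps group id -> member names and must partition the
    roster into groups of size 1 or 2; by default it is taken from the
    roster's pair annotations.  The merged matrix lives on a reduced roster
    whose entries keep the group's type and are named by the pair id.
    Mutual connections within a pair land on the diagonal of the collapsed
    matrix; binarized analyses drop them via the usual autapse exclusion.
    """
    roster = matrix.roster
    if pair_map is None:
        pair_map = roster.pair_map()
    members = [m for grp in pair_map.values() for m in grp]
    if sorted(members) != sorted(roster.names) or any(
        len(g) not in (1, 2) for g in pair_map.values()
    ):
        raise ValidationError("pair_map must partition the roster into groups of size <= 2")
    group_ids = list(pair_map)
    k = len(group_ids)
    G = np.zeros((k, len(roster)))
    merged_neurons = []
    for gi, gid in enumerate(group_ids):
        names = pair_map[gid]
        for nm in names:
            G[gi, roster.index(nm)] = 1.0
        merged_neurons.append(Neuron(gid, roster.type_of(names[0]), None))
    W = G @ matrix.W @ G.T
    return ConnectivityMatrix(Roster(merged_neurons), W, stage=matrix.stage,
                              normalized=matrix.normalized)


@dataclass
class ModulePartition:
    """Modules (neuron-name sets) with the partition's modularity score."""

    modules: list[set[str]]
    modularity: float
    excluded_singletons: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"neuron": name, "module_id": i}
            for i, mod in enumerate(self.modules)
            for name in sorted(mod)
        ]
        return pd.DataFrame(rows, columns=["neuron", "module_id"])


def detect_modules(
    matrix: ConnectivityMatrix, weighted: bool = False
) -> ModulePartition:
    """Greedy (Clauset–Newman–Moore) modularity communities.

    Runs on the undirected projection — binarized by default, weight-summed
    in ``weighted`` mode.  Self-loops (e.g. intra-pair connections after LR
    collapse) are ignored.  Modules of size 1 are excluded from the report.
    """
    W = matrix.W.copy()
    np.fill_diagonal(W, 0.0)
    U = W + W.T
    if not weighted:
        U = (U > 0).astype(float)
    G = nx.from_numpy_array(U)  # undirected
    G.remove_nodes_from([v for v in list(G) if G.degree(v) == 0])
    if G.number_of_edges() == 0:
        return ModulePartition([], float("nan"), [])
    weight_key = "weight" if weighted else None
    comms = nx.community.greedy_modularity_communities(G, weight=weight_key)
    score = nx.community.modularity(G, comms, weight=weight_key or "weight")
    names = matrix.roster.names
    modules, singles = [], []
    for c in comms:
        named = {names[v] for v in c}
        if len(named) == 1:
            singles.extend(named)
        else:
            modules.append(named)
    return ModulePartition(modules, float(score), sorted(singles))


def module_similarity(m1: set[str], m2: set[str]) -> float:
    """Jaccard index |intersection| / |union|; NaN when both sets empty."""
    m1, m2 = set(m1), set(m2)
    union = m1 | m2
    if not union:
        return float("nan")
    return len(m1 & m2) / len(union)


@dataclass
class HubReport:
    """Hub neurons and the ER-calibrated out-degree threshold."""

    hubs: list[str]
    threshold: float
    p: float
    reps: int
    seed: int | None


def detect_hubs(
    adj: np.ndarray,
    names: list[str] | None = None,
    reps: int = 100,
    seed: int | None = None,
) -> HubReport:
    """Out-degree hubs against matched directed ER random networks.

    The threshold is the mean over ``reps`` ER networks (same n, same edge
    probability |E|/(n(n-1))) of the maximum out-degree; hubs are neurons
    whose out-degree strictly exceeds it.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    adj = np.asarray(adj, dtype=bool).copy()
    np.fill_diagonal(adj, False)
    n = adj.shape[0]
    p = float(adj.sum() / (n * (n - 1))) if n > 1 else 0.0
    rng = np.random.default_rng(seed)
    # out-degrees of a directed ER graph are iid Binomial(n-1, p)
    maxima = rng.binomial(n - 1, p, size=(reps, n)).max(axis=1)
    threshold = float(maxima.mean())
    out_deg = adj.sum(axis=1)
    idx = np.nonzero(out_deg > threshold)[0]
    labels = names if names is not None else list(range(n))
    return HubReport([labels[i] for i in idx], threshold, p, reps, seed)
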