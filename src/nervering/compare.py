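"""Stage-ensemble set algebra and per-neuron comparison statistics.

A connection is an ordered (pre, post) name pair present in a binarized
stage matrix.  Stage-conserved connections are those present in every
dataset of the ensemble; stage-specific connections of a dataset are those
found in no other dataset.

Connection similarity between two datasets compares, for one neuron i, its
binary vectors of outgoing connections v_s1^i and v_s2^i:

    CS(v_s1^i, v_s2^i) = exp(-d(v_s1^i, v_s2^i))

with d the Euclidean distance, so CS = 1 for identical output sets and
decays toward 0 as the sets diverge.  For binary vectors d is the square
root of the Hamming distance.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConnectivityMatrix, StageEnsemble
from .errors import UnknownStageError, ValidationError


@dataclass
class ConnectionSet:
    """Set of ordered (pre, post) name pairs with stage provenance."""

    pairs: set[tuple[str, str]]
    stages: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, pair) -> bool:
        return pair in self.pairs

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(rows, columns=["pre", "post"])


def connection_set(matrix: ConnectivityMatrix, weight_floor: float = 0.0) -> ConnectionSet:
    """The binarized matrix as a set of named connections."""
    adj = matrix.binarize(weight_floor)
    names = matrix.roster.names
    ii, jj = np.nonzero(adj)
    pairs = {(names[i], names[j]) for i, j in zip(ii, jj)}
    return ConnectionSet(pairs, (matrix.stage,))


def stage_conserved(ensemble: StageEnsemble, weight_floor: float = 0.0) -> ConnectionSet:
    """Connections present in the intersection of all datasets."""
    stages = ensemble.stages
    if len(stages) < 1:
        raise ValidationError("empty ensemble")
    sets = [connection_set(ensemble[s], weight_floor).pairs for s in stages]
    core = set.intersection(*sets)
    return ConnectionSet(core, tuple(stages))


def stage_specific(
    ensemble: StageEnsemble, stage: str, weight_floor: float = 0.0
) -> tuple[ConnectionSet, float]:
    """Connections found only in ``stage``, plus their proportion.

    The proportion is the specific count divided by the stage's own
    connection count (NaN for a stage with no connections).
    """
    if stage not in ensemble.matrices:
        raise UnknownStageError(stage)
    own = connection_set(ensemble[stage], weight_floor).pairs
    others: set[tuple[str, str]] = set()
    for s in ensemble.stages:
        if s != stage:
            others |= connection_set(ensemble[s], weight_floor).pairs
    specific = own - others
    prop = len(specific) / len(own) if own else float("nan")
    return ConnectionSet(specific, (stage,)), prop


def common_out_connections(
    adjA: np.ndarray, adjB: np.ndarray, neuron: int
) -> float:
    """Count of outgoing connections of ``neuron`` present in both datasets.

    Neurons with no outgoing connection in either dataset are excluded from
    the analysis; for those the function returns NaN.
    """
    adjA = np.asarray(adjA, dtype=bool)
    adjB = np.asarray(adjB, dtype=bool)
    if adjA.shape != adjB.shape:
        raise ValidationError("adjacency shapes differ")
    a, b = adjA[neuron], adjB[neuron]
    if not a.any() and not b.any():
        return float("nan")
    return float(np.count_nonzero(a & b))


def connection_similarity(vecA: Sequence[float], vecB: Sequence[float]) -> float:
    """CS = exp(-Euclidean distance) between two connectivity vectors."""
    a = np.asarray(vecA, dtype=float)
    b = np.asarray(vecB, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"vector lengths differ: {a.shape} vs {b.shape}")
    return float(np.exp(-np.linalg.norm(a - b)))


def similarity_per_neuron(adjA: np.ndarray, adjB: np.ndarray) -> np.ndarray:
    """CS of each neuron's outgoing vectors between two datasets.

    NaN for neurons excluded by the no-output rule (no outgoing connection
    in either dataset).
    """
    adjA = np.asarray(adjA, dtype=bool)
    adjB = np.asarray(adjB, dtype=bool)
    if adjA.shape != adjB.shape:
        raise ValidationError("adjacency shapes differ")
    diff = np.count_nonzero(adjA != adjB, axis=1).astype(float)
    cs = np.exp(-np.sqrt(diff))
    excluded = ~(adjA.any(axis=1) | adjB.any(axis=1))
    cs[excluded] = np.nan
    return cs


def rank_sum_test(x: Sequence[float], y: Sequence[float], exact_below: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of rank permutations when both samples are small
    (< ``exact_below``) and tie-free; otherwise the normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("empty group after exclusions")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if max(len(x), len(y)) < exact_below and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


_METRICS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {}


def _metric_cs(adjA, adjB):
    return similarity_per_neuron(adjA, adjB)


def _metric_common(adjA, adjB):
    adjA = np.asarray(adjA, dtype=bool)
    adjB = np.asarray(adjB, dtype=bool)
    vals = (adjA & adjB).sum(axis=1).astype(float)
    excluded = ~(adjA.any(axis=1) | adjB.any(axis=1))
    vals[excluded] = np.nan
    return vals


_METRICS["cs"] = _metric_cs
_METRICS["common"] = _metric_common


@dataclass
class GroupComparison:
    """Per-neuron averaged metric for two groups of dataset pairs + test."""

    table: pd.DataFrame  # columns: neuron, ntype, group_a, group_b
    p_value: float
    metric: str


def pairwise_group_stat(
    ensemble: StageEnsemble,
    metric: str | Callable[[np.ndarray, np.ndarray], np.ndarray],
    group_a_pairs: Sequence[tuple[str, str]],
    group_b_pairs: Sequence[tuple[str, str]],
    pre_type: str | None = None,
    weight_floor: float = 0.0,
) -> GroupComparison:
    """Average a per-neuron pairwise metric within two groups of stage pairs
    and compare the groups with a two-sided rank-sum test.

    ``metric`` is ``"cs"`` (connection similarity), ``"common"`` (common
    outgoing connections) or a callable ``(adjA, adjB) -> per-neuron array``.
    A neuron's group value is the mean over the pairs where it is not
    excluded; neurons excluded from every pair of a group drop out of the
    test.  ``pre_type`` restricts the tested neurons to one presynaptic
    type.
    """
    fn = _METRICS[metric] if isinstance(metric, str) else metric
    metric_name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
    adjs = {s: ensemble[s].binarize(weight_floor) for s in ensemble.stages}

    def group_means(pairs):
        cols = []
        for s1, s2 in pairs:
            if s1 not in adjs or s2 not in adjs:
                raise UnknownStageError(f"{s1!r} vs {s2!r}")
            cols.append(fn(adjs[s1], adjs[s2]))
        stacked = np.vstack(cols)
        with warnings.catch_warnings():
            # neurons excluded from every pair of a group are all-NaN columns
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(stacked, axis=0)

    a_means = group_means(group_a_pairs)
    b_means = group_means(group_b_pairs)

    roster = ensemble.roster
    table = pd.DataFrame(
        {
            "neuron": roster.names,
            "ntype": roster.types(),
            "group_a": a_means,
            "group_b": b_means,
        }
    )
    if pre_type is not None:
        table = table[table["ntype"] == pre_type]
    p = rank_sum_test(table["group_a"].to_numpy(), table["group_b"].to_numpy())
    return GroupComparison(table.reset_index(drop=True), p, metric_name)


def exact_rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Brute-force two-sided rank-sum p by enumerating all group splits.

    Exhaustive permutation null over which observations belong to group x;
    meant for small samples and as an independent check of
    :func:`rank_sum_test`.
    """
    x = list(x)
    y = list(y)
    pooled = x + y
    ranks = stats.rankdata(pooled)
    nx_ = len(x)
    obs = ranks[:nx_].sum()
    mean = nx_ * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), nx_):
        s = ranks[list(combo)].sum()
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
        total += 1
    return count / total
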