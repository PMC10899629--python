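"""Core data model: neuron roster, synapse records, connectivity matrices.

Connectivity follows the convention used throughout comparative
connectomics of the nematode nerve ring: a *connection* is an ordered
(presynaptic, postsynaptic) neuron pair joined by at least one synapse, and
its weight is the sum of the sizes of all synapses between the pair.  One
presynaptic active zone may serve several postsynaptic partners (a polyadic
synapse), so several synapse records can share an ``active_zone_id``.

Weight normalisation divides every weight by the standard deviation of the
nonzero connection weights after discarding the top 5th percentile, which
makes weights comparable across datasets of different physical scale while
being robust to a few very large connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateScaleError,
    EmptyInputError,
    UnknownNeuronError,
    UnknownStageError,
    ValidationError,
)

NEURON_TYPES = ("sensory", "inter", "motor", "muscle", "glia")


@dataclass(frozen=True)
class Neuron:
    """A roster entry.

    Parameters
    ----------
    name : canonical neuron name (e.g. ``"ASGL"``).
    ntype : one of ``sensory``, ``inter``, ``motor``, ``muscle``, ``glia``.
    pair_id : left-right homolog group identifier, or ``None`` for neurons
        without a contralateral partner.
    """

    name: str
    ntype: str
    pair_id: str | None = None

    def __post_init__(self):
        if self.ntype not in NEURON_TYPES:
            raise ValidationError(
                f"unknown neuron type {self.ntype!r}; expected one of {NEURON_TYPES}"
            )


class Roster:
    """Ordered, immutable collection of neurons shared by all datasets."""

    def __init__(self, neurons: Sequence[Neuron]):
        neurons = tuple(neurons)
        names = [n.name for n in neurons]
        if len(set(names)) != len(names):
            dupes = {x for x in names if names.count(x) > 1}
            raise ValidationError(f"duplicate neuron names in roster: {sorted(dupes)}")
        groups: dict[str, int] = {}
        for n in neurons:
            if n.pair_id is not None:
                groups[n.pair_id] = groups.get(n.pair_id, 0) + 1
        bad = {k: v for k, v in groups.items() if v > 2}
        if bad:
            raise ValidationError(f"pair groups with more than 2 members: {bad}")
        self._neurons = neurons
        self._index = {n.name: i for i, n in enumerate(neurons)}

    def __len__(self) -> int:
        return len(self._neurons)

    def __iter__(self):
        return iter(self._neurons)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, i: int) -> Neuron:
        return self._neurons[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, Roster) and self._neurons == other._neurons

    def __hash__(self):
        return hash(self._neurons)

    @property
    def names(self) -> list[str]:
        return [n.name for n in self._neurons]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise UnknownNeuronError(name) from None

    def type_of(self, name: str) -> str:
        return self._neurons[self.index(name)].ntype

    def types(self) -> np.ndarray:
        """Neuron types as an object array aligned with roster order."""
        return np.array([n.ntype for n in self._neurons], dtype=object)

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for n in self._neurons:
            counts[n.ntype] = counts.get(n.ntype, 0) + 1
        return counts

    def pair_map(self) -> dict[str, list[str]]:
        """Map pair/group id -> member names; singletons get their own name."""
        groups: dict[str, list[str]] = {}
        for n in self._neurons:
            key = n.pair_id if n.pair_id is not None else n.name
            groups.setdefault(key, []).append(n.name)
        return groups

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [n.name for n in self._neurons],
                "ntype": [n.ntype for n in self._neurons],
                "pair_id": [n.pair_id if n.pair_id is not None else "" for n in self._neurons],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Roster":
        required = {"name", "ntype"}
        if not required.issubset(df.columns):
            raise ValidationError(f"roster table needs columns {sorted(required)}")
        neurons = []
        for row in df.itertuples(index=False):
            pid = getattr(row, "pair_id", None)
            if pid is not None and (pd.isna(pid) or pid == ""):
                pid = None
            neurons.append(Neuron(str(row.name), str(row.ntype), pid if pid is None else str(pid)))
        return cls(neurons)


@dataclass(frozen=True)
class SynapseRecord:
    """One (active zone -> postsynaptic partner) pairing with its size."""

    active_zone_id: str
    pre: str
    post: str
    size: float

    def __post_init__(self):
        if self.size < 0:
            raise ValidationError(f"negative synapse size {self.size} for {self.active_zone_id}")


def validate_records(records: Iterable[SynapseRecord]) -> list[SynapseRecord]:
    """Check the active-zone invariants: one record per (az, post), shared pre."""
    records = list(records)
    seen: dict[tuple[str, str], SynapseRecord] = {}
    pre_of: dict[str, str] = {}
    for r in records:
        key = (r.active_zone_id, r.post)
        if key in seen:
            raise ValidationError(f"duplicate (active_zone, post) record: {key}")
        seen[key] = r
        if r.active_zone_id in pre_of and pre_of[r.active_zone_id] != r.pre:
            raise ValidationError(
                f"active zone {r.active_zone_id} has conflicting presynaptic neurons"
            )
        pre_of[r.active_zone_id] = r.pre
    return records


@dataclass
class ConnectivityMatrix:
    """Stage-labelled weighted directed adjacency over a fixed roster.

    ``W[i, j]`` is the weight of the connection from roster neuron ``i``
    (presynaptic) to neuron ``j`` (postsynaptic).
    """

    roster: Roster
    W: np.ndarray
    stage: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.roster)
        if self.W.shape != (n, n):
            raise ValidationError(f"weight matrix shape {self.W.shape} != ({n}, {n})")
        if (self.W < 0).any():
            raise ValidationError("negative connection weights")

    def copy(self) -> "ConnectivityMatrix":
        return replace(self, W=self.W.copy())

    def binarize(self, weight_floor: float = 0.0, exclude_autapses: bool = True) -> np.ndarray:
        return binarize(self, weight_floor, exclude_autapses=exclude_autapses)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.roster.names, columns=self.roster.names)

    @property
    def n_connections(self) -> int:
        return int(np.count_nonzero(self.W))


@dataclass
class StageEnsemble:
    """Collection of per-stage connectivity matrices on one shared roster."""

    matrices: dict[str, ConnectivityMatrix]
    planted_truth: object | None = None

    def __post_init__(self):
        if not self.matrices:
            raise ValidationError("ensemble needs at least one stage")
        rosters = {id(m.roster) for m in self.matrices.values()}
        if len(rosters) > 1:
            first = next(iter(self.matrices.values())).roster
            for m in self.matrices.values():
                if m.roster != first:
                    raise ValidationError("all stages must share one roster")

    @property
    def roster(self) -> Roster:
        return next(iter(self.matrices.values())).roster

    @property
    def stages(self) -> list[str]:
        return list(self.matrices)

    def __getitem__(self, stage: str) -> ConnectivityMatrix:
        try:
            return self.matrices[stage]
        except KeyError:
            raise UnknownStageError(stage) from None

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)


def build_connectivity(
    records: Iterable[SynapseRecord],
    roster: Roster,
    stage: str = "",
    exclude_autapses: bool = True,
) -> ConnectivityMatrix:
    """Sum synapse sizes into a weighted connectivity matrix.

    ``W[pre, post]`` is the total size of all synapses from ``pre`` onto
    ``post``; neuron pairs with no synapse stay at 0.  Record order is
    irrelevant.  Autapse records (pre == post) are rejected when
    ``exclude_autapses`` is on.
    """
    n = len(roster)
    W = np.zeros((n, n))
    for r in records:
        i = roster.index(r.pre)
        j = roster.index(r.post)
        if r.size < 0:
            raise ValidationError(f"negative synapse size {r.size}")
        if i == j and exclude_autapses:
            continue
        W[i, j] += r.size
    return ConnectivityMatrix(roster, W, stage=stage)


def trimmed_sd(values: np.ndarray) -> float:
    """Population SD of values at or below their 95th percentile.

    The top 5th percentile (values strictly above the linear-interpolation
    95th percentile) is discarded before taking the SD, which removes the
    bias a few very large connections would otherwise introduce.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateScaleError("need at least 2 weights to normalize")
    cut = np.percentile(values, 95)
    kept = values[values <= cut]
    sd = float(np.std(kept))
    if sd == 0:
        raise DegenerateScaleError("trimmed weights have zero standard deviation")
    return sd


def normalize_weights(matrix: ConnectivityMatrix) -> tuple[ConnectivityMatrix, float]:
    """Divide all weights by the trimmed SD of the nonzero weights.

    Returns the normalised matrix and the scale factor (the divisor).
    Zeros are absent connections and never enter the statistic.
    """
    nz = matrix.W[matrix.W > 0]
    sd = trimmed_sd(nz)
    out = replace(matrix, W=matrix.W / sd, normalized=True)
    return out, sd


def binarize(
    matrix: ConnectivityMatrix | np.ndarray,
    weight_floor: float = 0.0,
    exclude_autapses: bool = True,
) -> np.ndarray:
    """Boolean adjacency: edge present iff weight strictly exceeds the floor.

    With ``weight_floor=0`` every positive connection is an edge.  A positive
    floor on a normalised matrix reproduces the wiring-diagram rule that
    drops edges with normalised weight at or below the mean individual
    synapse weight.
    """
    if weight_floor < 0:
        raise ValidationError(f"negative weight floor {weight_floor}")
    W = matrix.W if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    adj = W > weight_floor
    if exclude_autapses:
        adj = adj.copy()
        np.fill_diagonal(adj, False)
    return adj


def summarize_synapses(records: Iterable[SynapseRecord]) -> dict[str, float]:
    """Headline counts of a synapse table.

    Returns active-zone / synapse / connection counts, the mean and SD of
    postsynaptic partners per active zone, mean synapses per connection and
    the percentage of monadic (single-partner) active zones.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("no synapse records")
    by_az: dict[str, int] = {}
    connections: set[tuple[str, str]] = set()
    for r in records:
        by_az[r.active_zone_id] = by_az.get(r.active_zone_id, 0) + 1
        connections.add((r.pre, r.post))
    partners = np.array(list(by_az.values()), dtype=float)
    n_syn = len(records)
    n_az = len(by_az)
    n_conn = len(connections)
    return {
        "n_active_zones": n_az,
        "n_synapses": n_syn,
        "n_connections": n_conn,
        "mean_partners_per_az": n_syn / n_az,
        "sd_partners": float(np.std(partners)),
        "mean_synapses_per_connection": n_syn / n_conn,
        "pct_monadic": 100.0 * float(np.mean(partners == 1)),
    }
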