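"""Synthetic connectome and volume generators with planted ground truth.

The ensemble generator emulates the structure of an 11-dataset
developmental series of nerve-ring connectomes: a conserved core of
connections present in every stage, stage-specific connections unique to
one dataset (with the diapause stage carrying a far larger share, ~25%
versus ~9% elsewhere), partially shared connections covering random stage
subsets, roughly exponential out-degree distributions with a few hub
neurons, correlated left-right homolog rows, plus two planted diapause
effects: extra triangle-closing motor-motor connections and rewired
sensory outputs.

Construction is union-first: each neuron draws a geometric union
out-degree and a set of union targets, and every union edge is then
independently assigned to exactly one category (core / one-stage specific
/ partial with a random 2-10 stage subset).  Per-stage membership is
therefore an independent Bernoulli thinning of a geometric variable, so
per-stage out-degrees are geometric too, with an analytically known
survival slope.  All planted sets are recorded per-edge in a stage
membership map, from which the ground truth is derived exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ConnectivityMatrix,
    Neuron,
    Roster,
    StageEnsemble,
    SynapseRecord,
)
from .errors import GeometryError, ValidationError
from .volume import ActiveZone, LabeledVolume

DEFAULT_STAGES = (
    "L1-1", "L1-2", "L1-3", "L1-4", "L2", "L3", "L4",
    "adult-1", "adult-2", "adult-3", "dauer",
)


@dataclass
class EnsembleSpec:
    """Parameters of the synthetic stage ensemble.

    Defaults reproduce the study conditions of the dauer nerve-ring
    series: 180 neurons partitioned 69/73/38 into sensory/inter/motor, 83
    left-right pairs (97 merged groups), a conserved core of 317
    connections, 499 dauer-specific connections against a ~9% specific
    rate elsewhere, and a mean per-stage out-degree of 11 (about 2000
    connections per dataset).
    """

    n_sensory: int = 69
    n_inter: int = 73
    n_motor: int = 38
    n_lr_pairs: int = 83
    stages: tuple[str, ...] = DEFAULT_STAGES
    dauer_stage: str = "dauer"
    core_size: int = 317
    dauer_specific: int = 499
    other_specific_rate: float = 0.09
    mean_out_degree: float = 11.0
    n_hubs: int = 3
    hub_factor: float = 4.0
    weight_sigma: float = 1.0
    weight_scale: float = 1.0
    motor_triangle_boost: int = 60
    sensory_rewire_rate: float = 0.5
    lr_resample: float = 0.1
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.n_sensory + self.n_inter + self.n_motor

    def __post_init__(self):
        n = self.n_neurons
        if self.core_size + self.dauer_specific > n * (n - 1):
            raise ValidationError("infeasible spec: more planted edges than node pairs")
        for r in (self.other_specific_rate, self.sensory_rewire_rate, self.lr_resample):
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"rate {r} outside [0, 1]")
        if self.dauer_stage not in self.stages:
            raise ValidationError(f"{self.dauer_stage!r} not among stages")


@dataclass
class PlantedTruth:
    """Exact per-edge ground truth of a generated ensemble."""

    membership: dict[tuple[str, str], frozenset[str]]
    core: set[tuple[str, str]]
    specific: dict[str, set[tuple[str, str]]]
    union_degree_slope: float
    stage_degree_slopes: dict[str, float]
    hubs: list[str]
    rewired: list[tuple[str, str, str]]  # (neuron, lost target, gained target)
    boost_edges: set[tuple[str, str]]
    spec: EnsembleSpec


def default_roster(spec: EnsembleSpec | None = None) -> Roster:
    """Roster with the configured type partition and LR pair structure."""
    spec = spec or EnsembleSpec()
    counts = {"sensory": spec.n_sensory, "inter": spec.n_inter, "motor": spec.n_motor}
    # allocate LR pairs across types, as many as each type can hold
    pairs_per_type = {t: c // 2 for t, c in counts.items()}
    excess = sum(pairs_per_type.values()) - spec.n_lr_pairs
    if excess < 0:
        raise ValidationError("n_lr_pairs exceeds what the type counts allow")
    for t in sorted(pairs_per_type, key=pairs_per_type.get, reverse=True):
        take = min(excess, pairs_per_type[t])
        pairs_per_type[t] -= take
        excess -= take
    prefix = {"sensory": "SN", "inter": "IN", "motor": "MN"}
    neurons = []
    for t in ("sensory", "inter", "motor"):
        npairs = pairs_per_type[t]
        for i in range(npairs):
            pid = f"{prefix[t]}{i + 1:02d}"
            neurons.append(Neuron(pid + "L", t, pid))
            neurons.append(Neuron(pid + "R", t, pid))
        for i in range(counts[t] - 2 * npairs):
            neurons.append(Neuron(f"{prefix[t]}{npairs + i + 1:02d}", t, None))
    return Roster(neurons)


def _geom0_slope(p: float) -> float:
    """log-survival slope of a Geom0(p) variable: P(D>k) = (1-p)^(k+1)."""
    return math.log(1.0 - p)


def _thinned_p(p: float, r: float) -> float:
    """Parameter of a Geom0 after independent Bernoulli(r) thinning."""
    q = 1.0 - p
    return p / (p + r * q)


def gen_stage_ensemble(spec: EnsembleSpec | None = None) -> StageEnsemble:
    """Generate the 11-stage ensemble with planted ground truth."""
    spec = spec or EnsembleSpec()
    rng = np.random.default_rng(spec.seed)
    roster = default_roster(spec)
    n = len(roster)
    names = roster.names
    types = roster.types()
    stages = list(spec.stages)
    n_stages = len(stages)
    dauer = spec.dauer_stage
    others = [s for s in stages if s != dauer]

    # --- sizing: union edge count so stages hit the target mean degree ----
    target_stage_edges = spec.mean_out_degree * n
    spec_other = round(spec.other_specific_rate * target_stage_edges)
    dauer_reserved = max(0, spec.dauer_specific - spec.motor_triangle_boost)
    total_specific = spec_other * len(others) + dauer_reserved
    mean_subset = (
        np.mean(np.arange(2, n_stages)) / n_stages if n_stages > 2 else 1.0
    )  # coverage probability of a partial edge for one given stage
    mean_specific = total_specific / n_stages
    partial_total = max(
        0.0,
        (target_stage_edges - spec.core_size - mean_specific) / mean_subset,
    )
    union_total = spec.core_size + total_specific + partial_total
    # hubs draw hub_factor times the base mean; discount so the realized
    # union edge count stays near union_total
    hub_excess = spec.n_hubs * (spec.hub_factor - 1.0)
    mean_union_degree = union_total / (n + hub_excess)
    p_geom = 1.0 / (1.0 + mean_union_degree)  # Geom0: mean = (1-p)/p

    # --- union graph: geometric degrees, hubs, correlated LR rows ---------
    pair_map = roster.pair_map()
    secondary = {}  # index of R member -> index of L member
    for gid, members in pair_map.items():
        if len(members) == 2:
            secondary[roster.index(members[1])] = roster.index(members[0])
    primaries = np.array([u for u in range(n) if u not in secondary])
    hub_idx = rng.choice(primaries, size=spec.n_hubs, replace=False)

    union_targets: dict[int, np.ndarray] = {}
    for u in range(n):
        if u in secondary:
            continue
        mean_u = mean_union_degree * (spec.hub_factor if u in hub_idx else 1.0)
        p_u = 1.0 / (1.0 + mean_u)
        d = min(int(rng.geometric(p_u) - 1), n - 2)  # Geom0 = geometric - 1
        choices = np.setdiff1d(np.arange(n), [u])
        union_targets[u] = rng.choice(choices, size=d, replace=False)
    for u, l in secondary.items():
        base = union_targets[l].copy()
        base = base[base != u]
        resample = np.nonzero(rng.random(len(base)) < spec.lr_resample)[0]
        if len(resample):
            forbidden = set(base.tolist()) | {u}
            pool = np.array([v for v in range(n) if v not in forbidden])
            take = min(len(resample), len(pool))
            if take:
                idx = rng.choice(resample, size=take, replace=False)
                base[idx] = rng.choice(pool, size=take, replace=False)
        union_targets[u] = np.unique(base)

    union_edges = [(u, int(v)) for u, ts in union_targets.items() for v in ts]
    rng.shuffle(union_edges)
    if len(union_edges) < spec.core_size + total_specific:
        raise ValidationError("infeasible spec: union graph too sparse for planted sets")

    # --- categorize union edges ------------------------------------------
    membership: dict[tuple[int, int], set[str]] = {}
    cursor = 0
    for e in union_edges[cursor:cursor + spec.core_size]:
        membership[e] = set(stages)
    cursor += spec.core_size
    for s in others:
        for e in union_edges[cursor:cursor + spec_other]:
            membership[e] = {s}
        cursor += spec_other
    dauer_base = list(union_edges[cursor:cursor + dauer_reserved])
    for e in dauer_base:
        membership[e] = {dauer}
    cursor += dauer_reserved
    for e in union_edges[cursor:]:
        k = int(rng.integers(2, n_stages))  # subset of 2..n_stages-1 stages
        membership[e] = set(rng.choice(stages, size=k, replace=False).tolist())

    core_edges = set(union_edges[:spec.core_size])

    # --- planted diapause effect 1: sensory output rewiring ---------------
    # Replace a fraction of each sensory neuron's shared (non-core) dauer
    # targets with fresh dauer-only targets; compensate from the reserved
    # dauer-specific pool so the planted dauer-specific count is unchanged.
    rewired: list[tuple[int, int, int]] = []
    base_pool = [e for e in dauer_base if e in membership]
    sensory_idx = np.nonzero(types == "sensory")[0]
    out_sets = {u: {v for (uu, v) in membership if uu == u} for u in range(n)}
    for u in sensory_idx:
        candidates = [
            (u, v)
            for (uu, v), st in membership.items()
            if uu == u and dauer in st and (uu, v) not in core_edges and st != {dauer}
        ]
        for e in candidates:
            if rng.random() >= spec.sensory_rewire_rate:
                continue
            membership[e].discard(dauer)
            pool = [v for v in range(n) if v != u and v not in out_sets[u]]
            if not pool:
                continue
            t_new = int(pool[rng.integers(len(pool))])
            membership[(u, t_new)] = {dauer}
            out_sets[u].add(t_new)
            rewired.append((u, e[1], t_new))
            if base_pool:
                del membership[base_pool.pop()]

    # --- planted diapause effect 2: motor-motor triangle closures ----------
    motor_idx = np.nonzero(types == "motor")[0]
    dauer_adj = np.zeros((n, n), dtype=bool)
    for (u, v), st in membership.items():
        if dauer in st:
            dauer_adj[u, v] = True
    sub = dauer_adj[np.ix_(motor_idx, motor_idx)]
    und = sub | sub.T
    boost_edges: set[tuple[int, int]] = set()
    closure_candidates = []
    m = len(motor_idx)
    for a in range(m):
        for b in range(m):
            if a == b or und[a, b]:
                continue
            shared = int((und[a] & und[b]).sum())
            if shared:  # common neighbors -> each closes a triangle
                closure_candidates.append((shared, rng.random(), a, b))
    # prefer pairs closing the most triangles per added edge
    closure_candidates = [
        (a, b) for _, _, a, b in sorted(closure_candidates, reverse=True)
    ]
    for a, b in closure_candidates:
        if len(boost_edges) >= spec.motor_triangle_boost:
            break
        e = (int(motor_idx[a]), int(motor_idx[b]))
        if e in membership:
            continue
        membership[e] = {dauer}
        boost_edges.add(e)

    # --- top up dauer-specific connections to the planted count -----------
    def dauer_only_count():
        return sum(1 for st in membership.values() if st == {dauer})

    attempts = 0
    while dauer_only_count() < spec.dauer_specific and attempts < 100_000:
        u = int(rng.integers(n))
        v = int(rng.integers(n))
        if u != v and (u, v) not in membership:
            membership[(u, v)] = {dauer}
        attempts += 1

    # --- weights and matrices ---------------------------------------------
    matrices = {}
    mu = math.log(spec.weight_scale)
    for s in stages:
        W = np.zeros((n, n))
        for (u, v), st in membership.items():
            if s in st:
                W[u, v] = rng.lognormal(mean=mu, sigma=spec.weight_sigma)
        matrices[s] = ConnectivityMatrix(roster, W, stage=s)

    # --- exact planted truth from the membership map -----------------------
    named = {
        (names[u], names[v]): frozenset(st) for (u, v), st in membership.items() if st
    }
    core = {e for e, st in named.items() if st == frozenset(stages)}
    specific = {
        s: {e for e, st in named.items() if st == frozenset({s})} for s in stages
    }
    r_core = spec.core_size / union_total
    slopes = {}
    for s in stages:
        n_spec_s = dauer_reserved if s == dauer else spec_other
        r_s = r_core + n_spec_s / union_total + (partial_total / union_total) * mean_subset
        slopes[s] = _geom0_slope(_thinned_p(p_geom, r_s))
    truth = PlantedTruth(
        membership=named,
        core=core,
        specific=specific,
        union_degree_slope=_geom0_slope(p_geom),
        stage_degree_slopes=slopes,
        hubs=[names[i] for i in hub_idx],
        rewired=[(names[u], names[a], names[b]) for u, a, b in rewired],
        boost_edges={(names[u], names[v]) for u, v in boost_edges},
        spec=spec,
    )
    return StageEnsemble(matrices, planted_truth=truth)


def union_adjacency(ensemble: StageEnsemble) -> np.ndarray:
    """Boolean union of all stages' binarized matrices."""
    n = len(ensemble.roster)
    adj = np.zeros((n, n), dtype=bool)
    for s in ensemble.stages:
        adj |= ensemble[s].binarize()
    return adj


def gen_synapse_table(
    matrix: ConnectivityMatrix,
    polyady_mean: float = 2.26,
    synapses_per_connection: float = 2.90,
    seed: int | None = None,
) -> list[SynapseRecord]:
    """Decompose a connectivity matrix into a polyadic synapse table.

    Each connection's weight is split across 1 + Poisson draws of synapses
    whose sizes sum exactly to the weight; synapses of one presynaptic
    neuron are then grouped into active zones whose postsynaptic partner
    counts are 1 + Poisson(polyady_mean - 1) (capped by the number of
    distinct partners still available).  Rebuilding the matrix from the
    returned records recovers the input weights.
    """
    if polyady_mean < 1:
        raise ValidationError("polyady_mean must be >= 1")
    rng = np.random.default_rng(seed)
    names = matrix.roster.names
    records: list[SynapseRecord] = []
    az_counter = 0
    # An active zone's partners must be distinct, so its partner count is
    # capped by the presynaptic neuron's remaining distinct targets; a
    # proportional feedback on the running mean compensates for that cap
    # so the ensemble mean lands on polyady_mean.
    n_partners_total = 0
    n_az_total = 0
    order = rng.permutation(len(names))
    for i in order:
        pre = names[i]
        posts = np.nonzero(matrix.W[i])[0]
        if len(posts) == 0:
            continue
        # split each connection weight into synapse-sized parts
        pool: dict[int, list[float]] = {}
        for j in posts:
            w = matrix.W[i, j]
            k = 1 + rng.poisson(max(0.0, synapses_per_connection - 1.0))
            cuts = np.sort(rng.random(k - 1))
            parts = np.diff(np.concatenate([[0.0], cuts, [1.0]])) * w
            pool[int(j)] = list(parts)
        # group synapses into active zones, most-loaded partners first
        while pool:
            deficit = polyady_mean * n_az_total - n_partners_total
            lam = max(0.0, polyady_mean - 1.0 + deficit / 50.0)
            c = min(1 + rng.poisson(lam), len(pool))
            loads = np.array([len(v) for v in pool.values()])
            keys = np.array(list(pool.keys()))
            sel = np.lexsort((rng.random(len(keys)), -loads))
            chosen = keys[sel[:c]]
            az_counter += 1
            az_id = f"az{az_counter:06d}"
            for j in chosen:
                size = pool[int(j)].pop()
                records.append(SynapseRecord(az_id, pre, names[int(j)], size))
                if not pool[int(j)]:
                    del pool[int(j)]
            n_az_total += 1
            n_partners_total += int(c)
    return records


# ---------------------------------------------------------------------------
# labeled volumes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    """Axis-aligned voxel block: half-open bounds per axis."""

    name: str
    bounds: tuple[int, int, int, int, int, int]  # x0, x1, y0, y1, z0, z1

    def slices(self):
        x0, x1, y0, y1, z0, z1 = self.bounds
        return (slice(x0, x1), slice(y0, y1), slice(z0, z1))

    def overlap_1d(self, other: "Block", axis: int) -> int:
        a0, a1 = self.bounds[2 * axis], self.bounds[2 * axis + 1]
        b0, b1 = other.bounds[2 * axis], other.bounds[2 * axis + 1]
        return max(0, min(a1, b1) - max(a0, b0))


@dataclass
class VolumeSpec:
    """Blueprint of a synthetic labeled volume with analytic contacts."""

    shape: tuple[int, int, int]
    blocks: list[Block]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 50.0)
    active_zones: list[ActiveZone] = field(default_factory=list)
    mask_background: bool = False


def analytic_contact_table(spec: VolumeSpec) -> pd.DataFrame:
    """Closed-form pairwise face-contact areas of a block layout (nm^2)."""
    dx, dy, dz = spec.voxel_size
    face = {0: dy * dz, 1: dx * dz, 2: dx * dy}
    rows = []
    for i, a in enumerate(spec.blocks):
        for b in spec.blocks[i + 1:]:
            area = 0.0
            for axis in range(3):
                lo_a, hi_a = a.bounds[2 * axis], a.bounds[2 * axis + 1]
                lo_b, hi_b = b.bounds[2 * axis], b.bounds[2 * axis + 1]
                touching = hi_a == lo_b or hi_b == lo_a
                if not touching:
                    continue
                o1 = a.overlap_1d(b, (axis + 1) % 3)
                o2 = a.overlap_1d(b, (axis + 2) % 3)
                area += o1 * o2 * face[axis]
            rows.append({"cellA": a.name, "cellB": b.name, "area_nm2": area})
    return pd.DataFrame(rows, columns=["cellA", "cellB", "area_nm2"])


def gen_labeled_volume(spec: VolumeSpec) -> tuple[LabeledVolume, pd.DataFrame]:
    """Rasterize a block layout; returns the volume and the analytic areas."""
    labels = np.zeros(spec.shape, dtype=np.int32)
    label_map = {}
    for lab, block in enumerate(spec.blocks, start=1):
        sl = block.slices()
        if (labels[sl] != 0).any():
            raise GeometryError(f"block {block.name!r} overlaps an earlier block")
        for axis, (lo, hi) in enumerate(zip(block.bounds[::2], block.bounds[1::2])):
            if lo < 0 or hi > spec.shape[axis] or lo >= hi:
                raise GeometryError(f"block {block.name!r} bounds outside the grid")
        labels[sl] = lab
        label_map[lab] = block.name
    mask = (labels == 0) if spec.mask_background else None
    vol = LabeledVolume(
        labels,
        voxel_size=spec.voxel_size,
        label_map=label_map,
        mask=mask,
        active_zones={az.id: az for az in spec.active_zones},
    )
    return vol, analytic_contact_table(spec)


def two_block_volume(voxel_size=(2.0, 2.0, 50.0)) -> tuple[LabeledVolume, pd.DataFrame]:
    """Two 4x4x4 blocks abutting along x: contact = 16 faces of dy*dz."""
    spec = VolumeSpec(
        shape=(8, 4, 4),
        blocks=[Block("A", (0, 4, 0, 4, 0, 4)), Block("B", (4, 8, 0, 4, 0, 4))],
        voxel_size=voxel_size,
    )
    return gen_labeled_volume(spec)


def three_tube_volume(voxel_size=(2.0, 2.0, 50.0)) -> tuple[LabeledVolume, pd.DataFrame]:
    """Three parallel tubes along z; A-B and B-C touch, A-C never."""
    spec = VolumeSpec(
        shape=(6, 4, 10),
        blocks=[
            Block("A", (0, 2, 0, 3, 0, 10)),
            Block("B", (2, 4, 0, 3, 0, 10)),
            Block("C", (4, 6, 0, 3, 0, 10)),
        ],
        voxel_size=voxel_size,
    )
    return gen_labeled_volume(spec)


def twin_partner_volume(
    voxel_size=(2.0, 2.0, 50.0),
) -> tuple[LabeledVolume, dict[str, float]]:
    """Mirror-symmetric release geometry with two equivalent partners.

    A presynaptic slab carries an active zone at the symmetry plane of a
    cleft flanked by two mirror-image candidate cells, so the intended
    absorbed fractions are exactly (0.5, 0.5).
    """
    spec = VolumeSpec(
        shape=(21, 9, 7),
        blocks=[
            Block("PRE", (0, 21, 0, 3, 0, 7)),
            Block("LEFT", (0, 9, 3, 9, 0, 7)),
            Block("RIGHT", (12, 21, 3, 9, 0, 7)),
        ],
        voxel_size=voxel_size,
    )
    az = ActiveZone("az1", "PRE", [(10, 2, z) for z in range(2, 5)])
    spec.active_zones.append(az)
    vol, _ = gen_labeled_volume(spec)
    return vol, {"LEFT": 0.5, "RIGHT": 0.5}


def swollen_contact_volumes(
    footprints: tuple[tuple[int, int], tuple[int, int]] = ((8, 79), (10, 10)),
    voxel_size=(2.0, 2.0, 50.0),
) -> tuple[LabeledVolume, LabeledVolume, float]:
    """Two volumes whose A-B contact differs by a planted fold change.

    The A-B contact patch is a rectangle of ``wx * wz`` y-faces given by
    each volume's footprint; all other block contacts are identical, so
    the raw A-B fold change equals the face-count ratio exactly —
    (8*79) / (10*10) = 6.32 with the defaults, emulating a local process
    swelling in the diapause stage.
    """

    def build(wx, wz):
        blocks = [
            Block("A", (0, 24, 0, 3, 0, 90)),
            Block("B", (0, wx, 3, 6, 0, wz)),
            Block("C", (14, 18, 3, 6, 20, 24)),
        ]
        spec = VolumeSpec(shape=(24, 6, 90), blocks=blocks, voxel_size=voxel_size)
        return gen_labeled_volume(spec)[0]

    (ax, az_), (bx, bz) = footprints
    vol_a = build(ax, az_)
    vol_b = build(bx, bz)
    return vol_a, vol_b, (ax * az_) / (bx * bz)
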