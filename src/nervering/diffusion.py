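"""Monte-Carlo neurotransmitter diffusion for synaptic partner assignment.

For each active zone, particles are released into the extracellular space
adjacent to the release site and perform a lattice random walk through
unlabeled (label-0) voxels.  A particle is absorbed the first time it
steps into a voxel of any cell other than the presynaptic one; stepping
into the presynaptic cell leaves the particle in place; leaving the grid
or exceeding the step budget counts the particle as lost.  Postsynaptic
partners are the cells whose absorbed fraction (among non-lost particles)
reaches a threshold, and the active zone's size is split among accepted
partners in proportion to their fractions — polyadic synapses emerge
naturally wherever several cells border the cleft.

By default the six step directions are equiprobable.  Because EM sections
make voxels strongly anisotropic (e.g. 2 x 2 x 50 nm), an optional
anisotropy-weighted mode draws each axis with probability proportional to
1/spacing^2, the discretisation of isotropic diffusion on an anisotropic
grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import SynapseRecord
from .errors import GeometryError, ValidationError
from .volume import LabeledVolume

_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@dataclass
class DiffusionTally:
    """Absorption counts of one active zone's particle ensemble."""

    active_zone_id: str
    pre: str
    absorbed: dict[int, int]  # cell label -> particle count
    lost: int
    n_particles: int
    max_steps: int
    seed: int | None

    def __post_init__(self):
        if sum(self.absorbed.values()) + self.lost != self.n_particles:
            raise ValidationError("tally does not conserve particles")

    def fractions(self) -> dict[int, float]:
        """Absorbed fraction per cell label, over non-lost particles."""
        landed = self.n_particles - self.lost
        if landed == 0:
            return {}
        return {lab: c / landed for lab, c in self.absorbed.items()}


def release_sites(volume: LabeledVolume, active_zone_id: str) -> np.ndarray:
    """Label-0 voxels 6-adjacent to the active zone (the extracellular side)."""
    az = volume.active_zones[active_zone_id]
    shape = np.array(volume.labels.shape)
    cand = (az.voxels[:, None, :] + _STEPS[None, :, :]).reshape(-1, 3)
    ok = ((cand >= 0) & (cand < shape)).all(axis=1)
    cand = np.unique(cand[ok], axis=0)
    free = volume.labels[cand[:, 0], cand[:, 1], cand[:, 2]] == 0
    return cand[free]


def simulate_release(
    volume: LabeledVolume,
    active_zone_id: str,
    n_particles: int = 10_000,
    max_steps: int = 50_000,
    seed: int | None = None,
    anisotropic: bool = False,
) -> DiffusionTally:
    """Random-walk particle release from one active zone.

    Fully reproducible for a fixed seed.  Raises :class:`GeometryError`
    when the active zone has no extracellular-adjacent release voxel.
    """
    if active_zone_id not in volume.active_zones:
        raise ValidationError(f"unknown active zone {active_zone_id!r}")
    if n_particles < 1:
        raise ValidationError("n_particles must be >= 1")
    az = volume.active_zones[active_zone_id]
    pre_label = volume.label_of(az.pre)
    sites = release_sites(volume, active_zone_id)
    if len(sites) == 0:
        raise GeometryError(
            f"active zone {active_zone_id!r} has no extracellular release site"
        )
    rng = np.random.default_rng(seed)
    labels = volume.labels
    shape = np.array(labels.shape)

    if anisotropic:
        w = 1.0 / np.square(np.asarray(volume.voxel_size, dtype=float))
        probs = np.repeat(w / w.sum() / 2.0, 2)  # (+x,-x,+y,-y,+z,-z)
    else:
        probs = np.full(6, 1.0 / 6.0)

    pos = sites[rng.integers(0, len(sites), size=n_particles)]
    active = np.ones(n_particles, dtype=bool)
    absorbed_by = np.zeros(n_particles, dtype=np.int64)  # 0 = not absorbed
    lost = 0
    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        moves = _STEPS[rng.choice(6, size=len(idx), p=probs)]
        nxt = pos[idx] + moves
        inside = ((nxt >= 0) & (nxt < shape)).all(axis=1)
        # particles stepping off the grid escape the neuropil: lost
        out_ids = idx[~inside]
        lost += len(out_ids)
        active[out_ids] = False
        idx, nxt = idx[inside], nxt[inside]
        lab = labels[nxt[:, 0], nxt[:, 1], nxt[:, 2]]
        free = lab == 0
        hit_pre = lab == pre_label
        hit_cell = ~free & ~hit_pre
        move_ids = idx[free]
        pos[move_ids] = nxt[free]
        cell_ids = idx[hit_cell]
        absorbed_by[cell_ids] = lab[hit_cell]
        active[cell_ids] = False
        # particles stepping into the presynaptic cell stay put
    lost += int(active.sum())
    counts: dict[int, int] = {}
    for lab in absorbed_by[absorbed_by > 0]:
        counts[int(lab)] = counts.get(int(lab), 0) + 1
    return DiffusionTally(
        active_zone_id, az.pre, counts, lost, n_particles, max_steps, seed
    )


def assign_partners(
    tally: DiffusionTally,
    volume: LabeledVolume,
    az_size: float,
    min_fraction: float = 0.05,
) -> list[SynapseRecord]:
    """Turn a diffusion tally into synapse records.

    Cells whose absorbed fraction (of non-lost particles) reaches
    ``min_fraction`` become postsynaptic partners; the active-zone size is
    split among them in proportion to their fractions, renormalised so the
    assigned sizes sum exactly to ``az_size``.  Returns an empty list (with
    nothing assigned) when every particle was lost.
    """
    if not 0.0 <= min_fraction < 1.0:
        raise ValidationError(f"min_fraction {min_fraction} outside [0, 1)")
    if az_size < 0:
        raise ValidationError("az_size must be nonnegative")
    fracs = tally.fractions()
    if not fracs:
        warnings.warn(
            f"active zone {tally.active_zone_id!r}: every particle lost, "
            "no partner assigned",
            stacklevel=2,
        )
        return []
    accepted = {lab: f for lab, f in fracs.items() if f >= min_fraction}
    if not accepted:
        return []
    total = sum(accepted.values())
    records = []
    for lab in sorted(accepted):
        name = volume.label_map[lab]
        records.append(
            SynapseRecord(
                tally.active_zone_id, tally.pre, name, az_size * accepted[lab] / total
            )
        )
    return records
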