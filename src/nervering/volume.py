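"""Contact-area measurement on labeled voxel volumes.

Volumes are 3-D integer label grids with anisotropic physical voxel
dimensions (dx, dy, dz) in nm, axis order (x, y, z) with z the section
axis.  Two cells are in contact wherever their voxels share a face
(6-connectivity); each face-adjacent voxel pair contributes the area of
the shared face — dy*dz for x-neighbors, dx*dz for y-neighbors, dx*dy for
z-neighbors — so the contact area is the summed membrane apposition area.

Background masks (extracellular space left unlabeled by the segmentation)
are completed by repeated single-voxel dilation of the segments, visited
in a seeded pseudo-random order each round, until every mask voxel is
claimed; a voxel strictly closer to one segment is always claimed by it,
while ties are broken by the per-round visiting order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import trimmed_sd
from .errors import GeometryError, ResidualVoxelError, UnknownNeuronError, ValidationError

#: 6-connectivity structuring element
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class ActiveZone:
    """A presynaptic release site: id, presynaptic cell name, voxel list."""

    id: str
    pre: str
    voxels: np.ndarray  # (k, 3) integer voxel coordinates

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)


@dataclass
class LabeledVolume:
    """3-D labeled voxel grid with physical voxel dimensions.

    ``labels[x, y, z]`` holds an integer cell label; 0 is reserved for
    unassigned / extracellular space.  ``label_map`` maps label -> cell
    name.  ``mask`` optionally marks background voxels that should
    eventually be assigned to a segment.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 50.0)
    label_map: dict[int, str] = field(default_factory=dict)
    mask: np.ndarray | None = None
    active_zones: dict[str, ActiveZone] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("label grid must be 3-D")
        if any(d <= 0 for d in self.voxel_size):
            raise ValidationError(f"voxel dimensions must be positive: {self.voxel_size}")
        if 0 in self.label_map:
            raise ValidationError("label 0 is reserved for background")

    def label_of(self, name: str) -> int:
        for lab, nm in self.label_map.items():
            if nm == name:
                return lab
        raise UnknownNeuronError(name)

    @property
    def cell_names(self) -> list[str]:
        return [self.label_map[k] for k in sorted(self.label_map)]


def complete_background_mask(volume: LabeledVolume, seed: int | None = None) -> LabeledVolume:
    """Assign every background-mask voxel to a segment by iterative dilation.

    Each round visits the segments in a freshly shuffled pseudo-random
    order; a visited segment grows by one voxel (6-neighborhood) into the
    still-unclaimed mask.  Rounds repeat until the mask is covered.
    Original labeled voxels are never relabeled.  Raises
    :class:`ResidualVoxelError` if some mask voxels are unreachable.
    """
    if volume.mask is None:
        raise ValidationError("volume has no background mask")
    labels = volume.labels.copy()
    segs = sorted(set(np.unique(labels)) - {0})
    if not segs:
        raise ValidationError("volume has no labeled segment")
    remaining = volume.mask & (labels == 0)
    rng = np.random.default_rng(seed)
    while remaining.any():
        progress = False
        for seg in rng.permutation(segs):
            grown = ndimage.binary_dilation(labels == seg, structure=_STRUCT6) & remaining
            if grown.any():
                labels[grown] = seg
                remaining &= ~grown
                progress = True
        if not progress:
            raise ResidualVoxelError(int(remaining.sum()))
    return replace(volume, labels=labels, mask=volume.mask)


def _face_pairs(labels: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    sl_a = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    sl_a[axis] = slice(None, -1)
    sl_b[axis] = slice(1, None)
    return labels[tuple(sl_a)].ravel(), labels[tuple(sl_b)].ravel()


def _face_areas(voxel_size) -> np.ndarray:
    dx, dy, dz = voxel_size
    return np.array([dy * dz, dx * dz, dx * dy])


def contact_area(volume: LabeledVolume, cellA: str, cellB: str,
                 count_per_voxel: bool = False) -> float:
    """Summed shared-face area (nm^2) between two cells.

    Each face-adjacent voxel pair with labels (A, B) contributes the area
    of the shared face once; ``count_per_voxel`` counts it once per voxel
    instead (doubling all areas uniformly).
    """
    la = volume.label_of(cellA)
    lb = volume.label_of(cellB)
    if la == lb:
        return 0.0
    areas = _face_areas(volume.voxel_size)
    total = 0.0
    for axis in range(3):
        a, b = _face_pairs(volume.labels, axis)
        npairs = int(np.count_nonzero((a == la) & (b == lb))) + int(
            np.count_nonzero((a == lb) & (b == la))
        )
        total += npairs * areas[axis]
    return total * (2.0 if count_per_voxel else 1.0)


def contact_matrix(
    volume: LabeledVolume, names: list[str] | None = None
) -> pd.DataFrame:
    """All pairwise contact areas as a symmetric named matrix (nm^2)."""
    if names is None:
        names = volume.cell_names
    name_to_label = {volume.label_map[k]: k for k in volume.label_map}
    labs = np.array([name_to_label[nm] for nm in names])
    # dense relabeling for bincount: label value -> position (0 = ignore)
    lut = np.zeros(int(volume.labels.max()) + 1, dtype=np.int64)
    for pos, lab in enumerate(labs, start=1):
        if lab <= volume.labels.max():
            lut[lab] = pos
    k = len(names)
    M = np.zeros((k + 1, k + 1))
    areas = _face_areas(volume.voxel_size)
    for axis in range(3):
        a, b = _face_pairs(volume.labels, axis)
        pa, pb = lut[a], lut[b]
        sel = (pa > 0) & (pb > 0) & (pa != pb)
        if not sel.any():
            continue
        counts = np.bincount(pa[sel] * (k + 1) + pb[sel], minlength=(k + 1) ** 2)
        M += counts.reshape(k + 1, k + 1) * areas[axis]
    M = M[1:, 1:]
    M = M + M.T  # (A,B) and (B,A) face orientations
    return pd.DataFrame(M, index=names, columns=names)


def normalize_contact_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Divide all areas by the trimmed SD of the nonzero contact areas.

    Uses the same top-5th-percentile-trimmed population SD as connection
    weight normalisation (on the upper-triangle nonzero areas, each
    unordered pair counted once).
    """
    vals = matrix.to_numpy()
    iu = np.triu_indices_from(vals, k=1)
    nz = vals[iu][vals[iu] > 0]
    sd = trimmed_sd(nz)
    return matrix / sd, sd


def contact_fold_change(
    matrixA: pd.DataFrame, matrixB: pd.DataFrame, cellA: str, cellB: str
) -> float:
    """Ratio of (normalized) contact area in dataset A over dataset B.

    NaN when the denominator is zero.
    """
    a = float(matrixA.loc[cellA, cellB])
    b = float(matrixB.loc[cellA, cellB])
    if b == 0:
        return float("nan")
    return a / b
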