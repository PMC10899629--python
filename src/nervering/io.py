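"""Readers and writers for the package's table, matrix and volume formats.

Formats:

* synapse table — TSV/CSV with header columns ``active_zone_id``, ``pre``,
  ``post``, ``size`` (one row per active-zone/partner pairing);
* roster — CSV with ``name``, ``ntype``, ``pair_id`` (blank for unpaired);
* connectivity matrix — CSV, first row/column are roster names, rows are
  presynaptic;
* labeled volume — HDF5: ``labels`` dataset with ``voxel_size`` attribute,
  a label-map table, optional mask, and one voxel array per active zone;
* wiring diagram — GraphML with node types and per-edge weight plus an
  optional stage-difference annotation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .core import ConnectivityMatrix, Roster, SynapseRecord, validate_records
from .errors import ValidationError
from .volume import ActiveZone, LabeledVolume

SYNAPSE_COLUMNS = ["active_zone_id", "pre", "post", "size"]


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def read_synapse_table(path) -> list[SynapseRecord]:
    """Read and validate a synapse table (TSV or CSV by extension)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), encoding="utf-8")
    missing = [c for c in SYNAPSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    records = [
        SynapseRecord(str(r.active_zone_id), str(r.pre), str(r.post), float(r.size))
        for r in df.itertuples(index=False)
    ]
    return validate_records(records)


def write_synapse_table(records, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [(r.active_zone_id, r.pre, r.post, r.size) for r in records],
        columns=SYNAPSE_COLUMNS,
    )
    df.to_csv(path, sep=_sep_for(path), index=False, encoding="utf-8")


def read_roster_csv(path) -> Roster:
    return Roster.from_frame(pd.read_csv(path, dtype=str))


def write_roster_csv(roster: Roster, path) -> None:
    roster.to_frame().to_csv(path, index=False)


def read_matrix_csv(path, roster: Roster | None = None, stage: str = "") -> ConnectivityMatrix:
    """Matrix CSV with roster names as header row and index column."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column names differ")
    if roster is None:
        from .core import Neuron

        roster = Roster([Neuron(str(n), "inter") for n in df.index])
    elif list(df.index) != roster.names:
        raise ValidationError(f"{path}: matrix names do not match the roster")
    return ConnectivityMatrix(roster, df.to_numpy(dtype=float), stage=stage)


def write_matrix_csv(matrix: ConnectivityMatrix, path) -> None:
    matrix.to_frame().to_csv(path)


def write_volume(volume: LabeledVolume, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("labels", data=volume.labels, compression="gzip")
        d.attrs["voxel_size"] = np.asarray(volume.voxel_size, dtype=float)
        labs = sorted(volume.label_map)
        f.create_dataset("label_values", data=np.array(labs, dtype=np.int64))
        f.create_dataset(
            "label_names",
            data=np.array([volume.label_map[k] for k in labs], dtype=h5py.string_dtype()),
        )
        if volume.mask is not None:
            f.create_dataset("mask", data=volume.mask.astype(np.uint8), compression="gzip")
        az = f.create_group("active_zones")
        for az_id, zone in volume.active_zones.items():
            g = az.create_dataset(az_id, data=zone.voxels)
            g.attrs["pre"] = zone.pre


def read_volume(path) -> LabeledVolume:
    with h5py.File(path, "r") as f:
        labels = f["labels"][...]
        voxel_size = tuple(float(v) for v in f["labels"].attrs["voxel_size"])
        label_map = {
            int(v): n.decode() if isinstance(n, bytes) else str(n)
            for v, n in zip(f["label_values"][...], f["label_names"][...])
        }
        mask = f["mask"][...].astype(bool) if "mask" in f else None
        zones = {}
        for az_id in f["active_zones"]:
            d = f["active_zones"][az_id]
            pre = d.attrs["pre"]
            pre = pre.decode() if isinstance(pre, bytes) else str(pre)
            zones[az_id] = ActiveZone(az_id, pre, d[...])
    return LabeledVolume(labels, voxel_size, label_map, mask, zones)


def export_graphml(
    matrix: ConnectivityMatrix,
    path,
    weight_floor: float = 0.0,
    edge_annotations: dict[tuple[str, str], str] | None = None,
) -> None:
    """Write a wiring diagram: edges above the weight floor, typed nodes.

    ``weight_floor`` reproduces the diagram rule that drops edges whose
    normalized weight does not exceed the mean individual synapse weight.
    ``edge_annotations`` optionally tags connections (e.g. stage-specific /
    increased / decreased).
    """
    adj = matrix.binarize(weight_floor)
    names = matrix.roster.names
    G = nx.DiGraph()
    for n in matrix.roster:
        G.add_node(n.name, ntype=n.ntype)
    for i, j in zip(*np.nonzero(adj)):
        attrs = {"weight": float(matrix.W[i, j])}
        if edge_annotations:
            note = edge_annotations.get((names[i], names[j]))
            if note:
                attrs["change"] = note
        G.add_edge(names[i], names[j], **attrs)
    nx.write_graphml(G, path)


@dataclass
class RunConfig:
    """Round-trippable configuration of a pipeline run."""

    output_dir: str = "out"
    stage_labels: tuple[str, ...] = ()
    seed: int = 0
    weight_floor: float = 0.0
    min_fraction: float = 0.05
    er_reps: int = 1000
    vulnerability_reps: int = 100
    hub_reps: int = 100
    normalize: bool = True
    inputs: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.as_dict(), f, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["stage_labels"] = list(self.stage_labels)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        d["stage_labels"] = tuple(d.get("stage_labels", ()))
        return cls(**d)


def write_json(obj, path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_json_default)
        f.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
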