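"""Snapshot and configuration I/O.

A snapshot is a directory with two delimited-text tables and a JSON
sidecar:

* ``nodes.tsv`` — node_id, cell_id, role, ring_index, x, y, is_boundary
* ``cells.tsv`` — cell_id, layer, zone, polarization, wus, ck,
  cycle_progress, damping, target_area, edge_stiffness and the event
  counters (extras are preserved on read)
* ``meta.json`` — schema version, time, signal centres, apex, base frame,
  adhesion pairs and id counters (plus an optional config hash)

Floats are written with 17 significant digits so a write→read round trip
is exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .generate import GeneratorParams
from .growth import GrowthParams
from .signaling import SignalParams
from .simulate import SimConfig
from .tissue import Cell, MorseParams, Node, PotentialParams, SpringParams, Tissue

SCHEMA_VERSION = 1

NODE_COLUMNS = ["node_id", "cell_id", "role", "ring_index", "x", "y", "is_boundary"]
CELL_COLUMNS = [
    "cell_id",
    "layer",
    "zone",
    "polarization",
    "wus",
    "ck",
    "cycle_progress",
    "damping",
    "target_area",
    "edge_stiffness",
    "polarization_events",
    "division_events",
    "jitter_events",
]


class SnapshotError(ValueError):
    pass


def write_snapshot(tissue: Tissue, path: str | Path, config_hash: str | None = None) -> Path:
    """Write a lossless tissue snapshot to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    node_rows = []
    for nid, n in tissue.nodes.items():
        node_rows.append(
            {
                "node_id": nid,
                "cell_id": n.cell_id,
                "role": n.role,
                "ring_index": "" if n.ring_index is None else n.ring_index,
                "x": repr(float(n.position[0])),
                "y": repr(float(n.position[1])),
                "is_boundary": int(n.is_boundary),
            }
        )
    pd.DataFrame(node_rows, columns=NODE_COLUMNS).to_csv(path / "nodes.tsv", sep="\t", index=False)
    cell_rows = []
    for cid, c in tissue.cells.items():
        cell_rows.append(
            {
                "cell_id": cid,
                "layer": c.layer,
                "zone": c.zone,
                "polarization": c.polarization,
                "wus": repr(float(c.wus)),
                "ck": repr(float(c.ck)),
                "cycle_progress": repr(float(c.cycle_progress)),
                "damping": repr(float(c.damping)),
                "target_area": repr(float(c.target_area)),
                "edge_stiffness": ",".join(repr(float(v)) for v in c.edge_stiffness),
                "polarization_events": c.polarization_events,
                "division_events": c.division_events,
                "jitter_events": c.jitter_events,
            }
        )
    pd.DataFrame(cell_rows, columns=CELL_COLUMNS).to_csv(path / "cells.tsv", sep="\t", index=False)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "time_hours": tissue.time_hours,
        "wus_centre": None if tissue.wus_centre is None else [repr(v) for v in tissue.wus_centre.tolist()],
        "ck_centre": None if tissue.ck_centre is None else [repr(v) for v in tissue.ck_centre.tolist()],
        "apex": [repr(v) for v in tissue.apex.tolist()],
        "base_y": repr(tissue.base_y),
        "adhesion_pairs": sorted([list(p) for p in tissue.adhesion_pairs]),
        "wall_rings": {str(cid): c.wall_ring for cid, c in tissue.cells.items()},
        "next_node_id": tissue._next_node_id,
        "next_cell_id": tissue._next_cell_id,
        "config_hash": config_hash,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_snapshot(path: str | Path) -> Tissue:
    """Read a snapshot directory back into a Tissue (exact round trip)."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SnapshotError(f"{path}: missing meta.json")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SnapshotError(
            f"snapshot schema version {meta.get('schema_version')} != {SCHEMA_VERSION}"
        )
    try:
        nodes_df = pd.read_csv(path / "nodes.tsv", sep="\t", dtype=str)
        cells_df = pd.read_csv(path / "cells.tsv", sep="\t", dtype=str)
    except Exception as exc:
        raise SnapshotError(f"{path}: cannot parse tables ({exc})") from exc
    for col in NODE_COLUMNS:
        if col not in nodes_df.columns:
            raise SnapshotError(f"nodes.tsv: missing column {col!r}")
    t = Tissue()
    for i, row in nodes_df.iterrows():
        try:
            nid = int(row["node_id"])
            ring_index = None if pd.isna(row["ring_index"]) or row["ring_index"] == "" else int(float(row["ring_index"]))
            t.nodes[nid] = Node(
                position=np.array([float(row["x"]), float(row["y"])]),
                role=row["role"],
                cell_id=int(row["cell_id"]),
                ring_index=ring_index,
                is_boundary=bool(int(row["is_boundary"])),
            )
        except (TypeError, ValueError) as exc:
            raise SnapshotError(f"nodes.tsv line {i + 2}: {exc}") from exc
    rings = {int(k): v for k, v in meta["wall_rings"].items()}
    extras = [c for c in cells_df.columns if c not in CELL_COLUMNS]
    for i, row in cells_df.iterrows():
        try:
            cid = int(row["cell_id"])
            ring = rings[cid]
            cyt = {
                nid
                for nid, n in t.nodes.items()
                if n.cell_id == cid and n.role == "cytoplasm"
            }
            cell = Cell(
                id=cid,
                wall_ring=ring,
                cytoplasm=cyt,
                layer=row["layer"],
                zone=row["zone"],
                polarization=row["polarization"],
                wus=float(row["wus"]),
                ck=float(row["ck"]),
                cycle_progress=float(row["cycle_progress"]),
                damping=float(row["damping"]),
                target_area=float(row["target_area"]),
                edge_stiffness=np.array([float(v) for v in str(row["edge_stiffness"]).split(",")]),
                polarization_events=int(row["polarization_events"]),
                division_events=int(row["division_events"]),
                jitter_events=int(row["jitter_events"]),
            )
            if extras:  # foreign columns preserved as opaque extras
                cell.extras = {c: row[c] for c in extras}
            t.cells[cid] = cell
        except KeyError as exc:
            raise SnapshotError(f"cells.tsv line {i + 2}: missing ring for cell ({exc})") from exc
        except (TypeError, ValueError) as exc:
            raise SnapshotError(f"cells.tsv line {i + 2}: {exc}") from exc
    t.adhesion_pairs = {tuple(p) for p in meta["adhesion_pairs"]}
    t.wus_centre = None if meta["wus_centre"] is None else np.array([float(v) for v in meta["wus_centre"]])
    t.ck_centre = None if meta["ck_centre"] is None else np.array([float(v) for v in meta["ck_centre"]])
    t.apex = np.array([float(v) for v in meta["apex"]])
    t.base_y = float(meta["base_y"])
    t.time_hours = float(meta["time_hours"])
    t._next_node_id = int(meta["next_node_id"])
    t._next_cell_id = int(meta["next_cell_id"])
    t.validate()
    return t


def tissues_equal(a: Tissue, b: Tissue) -> bool:
    """Exact structural and positional equality of two tissues."""
    if set(a.nodes) != set(b.nodes) or set(a.cells) != set(b.cells):
        return False
    for nid in a.nodes:
        na, nb = a.nodes[nid], b.nodes[nid]
        if (
            not np.array_equal(na.position, nb.position)
            or na.role != nb.role
            or na.cell_id != nb.cell_id
            or na.ring_index != nb.ring_index
            or na.is_boundary != nb.is_boundary
        ):
            return False
    for cid in a.cells:
        ca, cb = a.cells[cid], b.cells[cid]
        if (
            ca.wall_ring != cb.wall_ring
            or ca.cytoplasm != cb.cytoplasm
            or ca.layer != cb.layer
            or ca.zone != cb.zone
            or ca.polarization != cb.polarization
            or ca.wus != cb.wus
            or ca.ck != cb.ck
            or ca.cycle_progress != cb.cycle_progress
            or not np.array_equal(ca.edge_stiffness, cb.edge_stiffness)
        ):
            return False
    return a.adhesion_pairs == b.adhesion_pairs and a.time_hours == b.time_hours


# ----------------------------------------------------------------------
# configuration files
# ----------------------------------------------------------------------

def config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    table = d["growth"]["periclinal_table"]
    d["growth"]["periclinal_table"] = {f"{z}/{g}": p for (z, g), p in table.items()}
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    pot = d.pop("potentials", {})
    growth = dict(d.pop("growth", {}))
    sig = d.pop("signaling", {})
    gen = d.pop("generator", {})
    if "periclinal_table" in growth:
        growth["periclinal_table"] = {
            tuple(k.split("/")): float(v) for k, v in growth["periclinal_table"].items()
        }
    potentials = PotentialParams(
        **{
            k: (
                MorseParams(**v)
                if k in ("turgor", "volume_exclusion", "pressure")
                else SpringParams(**v)
                if k in ("extensibility", "adhesion")
                else v
            )
            for k, v in pot.items()
        }
    )
    return SimConfig(
        potentials=potentials,
        growth=GrowthParams(**growth),
        signaling=SignalParams(**sig),
        generator=GeneratorParams(**gen),
        **d,
    )


def write_config(cfg: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def read_config(path: str | Path) -> SimConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
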