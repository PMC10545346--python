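"""CSV/JSON/OFF schemas shared by the pipeline.

Units everywhere: positions in micrometres, times in hours, angles in
radians (counterclockwise from the anterior-posterior +x axis).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .correlations import CorrelationCurve
from .kinetics import DivisionEvent, LineageForest
from .tessellation import CellSnapshot

SNAPSHOT_COLUMNS = ["frame", "time_h", "cell_id", "x", "y"]
DIVISION_COLUMNS = ["time_h", "x_um", "y_um", "theta_rad", "wave_label",
                    "parasegment", "parent_id", "daughter1_id", "daughter2_id"]
EDGE_COLUMNS = ["frame", "cell_id", "next_frame", "next_cell_id"]


def write_snapshots(snapshots: Sequence[CellSnapshot], path: str | Path) -> None:
    rows = []
    for fi, snap in enumerate(snapshots):
        for cid, (x, y) in zip(snap.ids, snap.positions):
            rows.append((fi, snap.time, int(cid), float(x), float(y)))
    pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS).to_csv(path, index=False)


def read_snapshots(path: str | Path) -> list[CellSnapshot]:
    df = pd.read_csv(path)
    _require_columns(df, SNAPSHOT_COLUMNS, path)
    out = []
    for fi, grp in df.groupby("frame", sort=True):
        out.append(CellSnapshot(time=float(grp["time_h"].iloc[0]),
                                ids=grp["cell_id"].to_numpy(int),
                                positions=grp[["x", "y"]].to_numpy(float)))
    return out


def write_divisions(events: Sequence[DivisionEvent], path: str | Path) -> None:
    rows = [(e.time, e.x, e.y, e.theta, e.wave, e.parasegment, e.parent_id,
             e.daughter_ids[0], e.daughter_ids[1]) for e in events]
    pd.DataFrame(rows, columns=DIVISION_COLUMNS).to_csv(path, index=False)


def read_divisions(path: str | Path) -> list[DivisionEvent]:
    df = pd.read_csv(path)
    _require_columns(df, DIVISION_COLUMNS, path)
    events = []
    for i, row in df.iterrows():
        if int(row.daughter1_id) == int(row.daughter2_id):
            raise ValueError(f"{path}, row {i}: daughters share id {int(row.daughter1_id)}")
        events.append(DivisionEvent(
            time=float(row.time_h), x=float(row.x_um), y=float(row.y_um),
            theta=float(row.theta_rad), parent_id=int(row.parent_id),
            daughter_ids=(int(row.daughter1_id), int(row.daughter2_id)),
            wave=str(row.wave_label), parasegment=int(row.parasegment)))
    return events


def write_lineage_edges(forest: LineageForest, path: str | Path) -> None:
    rows = [(f, c, nf, nc) for (c, f), (nc, nf) in forest.graph.edges]
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, index=False)


def load_tracks(snapshot_path: str | Path,
                edges_path: str | Path) -> tuple[LineageForest, list[CellSnapshot]]:
    """Rebuild a lineage forest and snapshot series from the CSV pair.

    Snapshot rows define the nodes (with positions and times); the edge
    file defines same-cell continuations and parent->daughter links.
    Schema violations raise with the offending row and column.
    """
    import warnings

    snapshots = read_snapshots(snapshot_path)
    forest = LineageForest()
    for fi, snap in enumerate(snapshots):
        for cid, pos in zip(snap.ids, snap.positions):
            forest.add_node(int(cid), fi, pos, snap.time)
    df = pd.read_csv(edges_path)
    _require_columns(df, EDGE_COLUMNS, edges_path)
    if df.empty:
        warnings.warn(f"{edges_path}: no lineage edges (empty file with header)")
    for i, row in df.iterrows():
        node = (int(row.cell_id), int(row.frame))
        nxt = (int(row.next_cell_id), int(row.next_frame))
        for n, col in ((node, "cell_id"), (nxt, "next_cell_id")):
            if n not in forest.graph:
                raise ValueError(f"{edges_path}, row {i}, column {col}: "
                                 f"node {n} absent from the snapshot table")
        forest.add_edge(node[0], node[1], nxt[0], nxt[1])
    forest.validate()
    return forest, snapshots


def write_curve(curve: CorrelationCurve, path: str | Path,
                sidecar: dict | None = None) -> None:
    df = pd.DataFrame({
        "kind": curve.kind,
        "r_lo": curve.r_edges[:-1],
        "r_hi": curve.r_edges[1:],
        "value": curve.values,
        "n_pairs": curve.counts,
    })
    df.to_csv(path, index=False)
    if sidecar is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def write_velocities(points: np.ndarray, vectors: np.ndarray, path: str | Path,
                     provenance: str, ids: np.ndarray | None = None) -> None:
    if ids is None:
        ids = np.arange(len(points))
    pd.DataFrame({
        "cell_id": ids, "x": points[:, 0], "y": points[:, 1],
        "vx": vectors[:, 0], "vy": vectors[:, 1], "provenance": provenance,
    }).to_csv(path, index=False)


def write_tissue_off(tissue, path: str | Path) -> None:
    """Final vertex-model tissue as a polygonal OFF file."""
    lines = ["OFF", f"{len(tissue.vertices)} {len(tissue.cells)} 0"]
    for v in tissue.vertices:
        lines.append(f"{v[0]:.10g} {v[1]:.10g} 0")
    for cyc in tissue.cells:
        lines.append(" ".join(str(x) for x in [len(cyc)] + list(cyc)))
    Path(path).write_text("\n".join(lines) + "\n")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
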