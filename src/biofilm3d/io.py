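"""Volume, table and lineage I/O.

Volumes are multi-page TIFF stacks in ZYX plane order: label volumes as
unsigned 16-bit integers (32-bit beyond 65,534 objects), intensity volumes
as 32-bit floats.  Lineages are written as two CSV tables (vertices, edges)
plus a cell-tracking-challenge-style track text file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tracking import PARENT, TRACK, CellVertex, LineageEdge, LineageGraph

log = logging.getLogger("biofilm3d")

__all__ = [
    "read_volume",
    "write_labels",
    "write_intensity",
    "write_lineage",
    "read_lineage",
    "write_tracks_ctc",
]

LABEL16_MAX = 65_534


def read_volume(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF stack as a 3D ZYX array.

    Integer stacks are returned as unsigned integer labels, float stacks as
    float32 intensities; values are never remapped.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        out = arr.astype(np.uint32 if arr.max() > LABEL16_MAX else np.uint16)
    elif np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float32)
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    log.info("read %s: shape=%s dtype=%s", path, out.shape, out.dtype)
    return out


def write_labels(labels: np.ndarray, path: str | Path, force_16bit: bool = False) -> None:
    """Write a label volume as 16-bit TIFF (32-bit when labels exceed 65,534)."""
    mx = int(labels.max()) if labels.size else 0
    if mx > LABEL16_MAX:
        if force_16bit:
            raise ValueError(f"label overflow: {mx} labels exceed the 16-bit cap")
        dtype = np.uint32
    else:
        dtype = np.uint16
    tifffile.imwrite(str(path), labels.astype(dtype), photometric="minisblack")


def write_intensity(image: np.ndarray, path: str | Path) -> None:
    """Write an intensity volume as 32-bit float TIFF."""
    tifffile.imwrite(str(path), image.astype(np.float32), photometric="minisblack")


def write_lineage(graph: LineageGraph, outdir: str | Path) -> None:
    """Write a lineage graph as vertices.csv + edges.csv + tracks.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vrows = [
        {
            "frame": v.frame, "id": v.id,
            "z": v.centroid[0], "y": v.centroid[1], "x": v.centroid[2],
            "volume": v.volume, "length": v.length,
        }
        for v in sorted(graph.vertices.values(), key=lambda v: (v.frame, v.id))
    ]
    pd.DataFrame(vrows).to_csv(outdir / "vertices.csv", index=False)
    erows = [
        {
            "src_frame": e.src[0], "src_id": e.src[1],
            "dst_frame": e.dst[0], "dst_id": e.dst[1],
            "semantics": e.semantics,
        }
        for e in graph.edges
    ]
    pd.DataFrame(erows, columns=["src_frame", "src_id", "dst_frame", "dst_id",
                                 "semantics"]).to_csv(outdir / "edges.csv", index=False)
    write_tracks_ctc(graph, outdir / "tracks.txt")


def read_lineage(outdir: str | Path) -> LineageGraph:
    """Read a lineage graph written by :func:`write_lineage`."""
    outdir = Path(outdir)
    vdf = pd.read_csv(outdir / "vertices.csv")
    edf = pd.read_csv(outdir / "edges.csv")
    graph = LineageGraph()
    for r in vdf.itertuples():
        graph.vertices[(int(r.frame), int(r.id))] = CellVertex(
            int(r.frame), int(r.id), (float(r.z), float(r.y), float(r.x)),
            float(r.volume), float(r.length),
        )
    for r in edf.itertuples():
        graph.edges.append(
            LineageEdge((int(r.src_frame), int(r.src_id)),
                        (int(r.dst_frame), int(r.dst_id)), str(r.semantics))
        )
    return graph


def write_tracks_ctc(graph: LineageGraph, path: str | Path) -> None:
    """Cell-tracking-challenge-style track summary.

    One line per track: ``track_id start_frame end_frame parent_track_id``
    (0 when the track has no parent).  A track is a maximal chain of track
    edges; parent-daughter edges start new tracks.
    """
    succ = {e.src: e.dst for e in graph.edges if e.semantics == TRACK}
    pred = {e.dst: e.src for e in graph.edges if e.semantics == TRACK}
    parent_edge = {e.dst: e.src for e in graph.edges if e.semantics == PARENT}
    starts = sorted(k for k in graph.vertices if k not in pred)
    track_id_of: dict[tuple[int, int], int] = {}
    tracks = []
    for tid, start in enumerate(starts, start=1):
        node = start
        while True:
            track_id_of[node] = tid
            if node not in succ:
                break
            node = succ[node]
        tracks.append((tid, start, node))
    lines = []
    for tid, start, end in tracks:
        parent_tid = 0
        if start in parent_edge:
            parent_tid = track_id_of[parent_edge[start]]
        lines.append(f"{tid} {start[0]} {end[0]} {parent_tid}")
    Path(path).write_text("\n".join(lines) + "\n")
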