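"""Tracking-by-detection across labelled frames and lineage-graph construction.

Detections (cells in one frame) are linked across consecutive frames by a
greedy nearest-neighbour rule — closest centroid pairs first, both endpoints
used at most once, no link beyond a maximum distance (1 µm for simulated
data, 1.5 µm for experimental).  Detections left unlinked are tested for a
division: a parent in the previous frame must lie within the distance
threshold and be at least 1.5× larger in volume and 1.5× longer than the
daughter.  A division rewrites the parent's surviving track link into a
second parent-daughter edge, so a division always yields two daughter edges.

The result is a lineage graph: an acyclic oriented graph whose vertices are
detections and whose edges are typed ``track`` (same cell over time) or
``parent-daughter``.  The module also computes the relative-movement (RM)
difficulty metric: per cell, frame-to-frame displacement over the distance
to the nearest *other* cell in the next frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .sim import ColonyFrame

__all__ = [
    "TrackingConfig",
    "CellVertex",
    "LineageEdge",
    "LineageGraph",
    "vertices_from_labels",
    "link_frames",
    "detect_divisions",
    "build_lineage",
    "relative_movement",
    "lineage_from_colony",
]

TRACK = "track"
PARENT = "parent-daughter"

VertexKey = tuple[int, int]  # (frame, cell id)


@dataclass(frozen=True)
class CellVertex:
    """One detection: a cell instance in one frame (centroid in µm, ZYX)."""

    frame: int
    id: int
    centroid: tuple[float, float, float]
    volume: float
    length: float


@dataclass(frozen=True)
class LineageEdge:
    src: VertexKey
    dst: VertexKey
    semantics: str  # TRACK or PARENT


@dataclass
class LineageGraph:
    """Acyclic oriented graph of detections over time."""

    vertices: dict[VertexKey, CellVertex] = field(default_factory=dict)
    edges: list[LineageEdge] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return sorted({k[0] for k in self.vertices})

    def frame_vertices(self, frame: int) -> list[CellVertex]:
        return sorted(
            (v for k, v in self.vertices.items() if k[0] == frame), key=lambda v: v.id
        )

    def edge_set(self) -> dict[tuple[VertexKey, VertexKey], str]:
        return {(e.src, e.dst): e.semantics for e in self.edges}

    def validate(self) -> None:
        """Check the structural invariants of a lineage graph."""
        frames = self.frames
        nxt = {f: frames[i + 1] for i, f in enumerate(frames[:-1])}
        incoming: dict[VertexKey, int] = {}
        out_track: dict[VertexKey, int] = {}
        out_parent: dict[VertexKey, int] = {}
        for e in self.edges:
            if e.src not in self.vertices or e.dst not in self.vertices:
                raise ValueError(f"edge references unknown vertex: {e}")
            if nxt.get(e.src[0]) != e.dst[0]:
                raise ValueError(f"edge must span consecutive frames: {e}")
            incoming[e.dst] = incoming.get(e.dst, 0) + 1
            if e.semantics == TRACK:
                out_track[e.src] = out_track.get(e.src, 0) + 1
            elif e.semantics == PARENT:
                out_parent[e.src] = out_parent.get(e.src, 0) + 1
            else:
                raise ValueError(f"unknown edge semantics {e.semantics!r}")
        if any(n > 1 for n in incoming.values()):
            raise ValueError("a vertex has more than one incoming edge")
        if any(n > 1 for n in out_track.values()):
            raise ValueError("a vertex has more than one outgoing track edge")
        if any(n > 2 for n in out_parent.values()):
            raise ValueError("a vertex has more than two daughters")
        both = set(out_track) & set(out_parent)
        if both:
            raise ValueError(f"vertices with mixed outgoing edge semantics: {both}")

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for k, v in self.vertices.items():
            g.add_node(k, centroid=v.centroid, volume=v.volume, length=v.length)
        for e in self.edges:
            g.add_edge(e.src, e.dst, semantics=e.semantics)
        return g


def vertices_from_labels(
    labels: np.ndarray,
    frame: int,
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1),
) -> list[CellVertex]:
    """Detections from a label volume: centroid/volume/length in physical units."""
    vs = np.asarray(voxel_size, float)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    objects = ndimage.find_objects(labels)
    out = []
    for k in ids:
        sl = objects[int(k) - 1]
        pts = np.argwhere(labels[sl] == k).astype(float)
        pts += [s.start for s in sl]
        pts_um = pts * vs
        centroid = tuple(pts_um.mean(axis=0))
        volume = float(len(pts) * vs.prod())
        cov = np.cov(pts_um.T, bias=True) + np.diag(vs**2) / 12.0
        length = float(4.0 * np.sqrt(max(np.linalg.eigvalsh(cov).max(), 0.0)))
        out.append(CellVertex(frame, int(k), centroid, volume, length))
    return out


@dataclass(frozen=True)
class TrackingConfig:
    """Nearest-neighbour linking and division-detection thresholds.

    Defaults suit simulated data (1 µm max link distance); use 1.5 µm for
    experimental stacks.  A parent must be ``volume_ratio`` times larger and
    ``length_ratio`` times longer than a candidate daughter.
    """

    max_link_distance: float = 1.0
    division_max_distance: float = 1.0
    volume_ratio: float = 1.5
    length_ratio: float = 1.5

    def __post_init__(self) -> None:
        if min(self.max_link_distance, self.division_max_distance,
               self.volume_ratio, self.length_ratio) <= 0:
            raise ValueError("all tracking thresholds must be positive")


def link_frames(
    frame_a: list[CellVertex],
    frame_b: list[CellVertex],
    cfg: TrackingConfig | None = None,
) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour links (a_id, b_id) between two frames.

    All centroid pairs within ``max_link_distance`` are sorted by distance
    (ties by smaller a-id then b-id) and accepted while both endpoints are
    unused.
    """
    cfg = cfg or TrackingConfig()
    if not frame_a or not frame_b:
        return []
    ca = np.array([v.centroid for v in frame_a])
    cb = np.array([v.centroid for v in frame_b])
    dist = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    cand = [
        (dist[i, j], frame_a[i].id, frame_b[j].id)
        for i in range(len(frame_a))
        for j in range(len(frame_b))
        if dist[i, j] <= cfg.max_link_distance
    ]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    links = []
    for _, aid, bid in cand:
        if aid in used_a or bid in used_b:
            continue
        links.append((aid, bid))
        used_a.add(aid)
        used_b.add(bid)
    return links


def detect_divisions(
    unlinked_b: list[CellVertex],
    linked_tracks: list[tuple[int, int]],
    frame_a: list[CellVertex],
    cfg: TrackingConfig | None = None,
) -> list[tuple[int, int]]:
    """Parent-daughter assignments (a_id, b_id) for unlinked detections.

    The nearest frame-a cell within ``division_max_distance`` that satisfies
    both ratio rules becomes the parent; when the chosen parent also carries
    a track link into frame b, that link is reinterpreted as the second
    daughter edge (callers rewrite its semantics).  No parent acquires more
    than two daughters.
    """
    cfg = cfg or TrackingConfig()
    by_id = {v.id: v for v in frame_a}
    track_of = dict(linked_tracks)
    daughters: dict[int, int] = {}
    out = []
    for b in sorted(unlinked_b, key=lambda v: v.id):
        best = None
        for a in frame_a:
            if a.volume < cfg.volume_ratio * b.volume - 1e-12:
                continue
            if a.length < cfg.length_ratio * b.length - 1e-12:
                continue
            n_daughters = daughters.get(a.id, 0) + (1 if a.id in track_of else 0)
            if n_daughters >= 2:
                continue
            dd = float(np.linalg.norm(np.subtract(a.centroid, b.centroid)))
            if dd > cfg.division_max_distance:
                continue
            if best is None or (dd, a.id) < best[:2]:
                best = (dd, a.id)
        if best is not None:
            aid = best[1]
            out.append((aid, b.id))
            daughters[aid] = daughters.get(aid, 0) + 1
            _ = by_id  # parents indexed by id for clarity
    return out


def build_lineage(
    frames: list[list[CellVertex]] | list[np.ndarray],
    cfg: TrackingConfig | None = None,
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1),
    frame_indices: list[int] | None = None,
) -> LineageGraph:
    """Track detections across frames into a lineage graph.

    ``frames`` may be per-frame label volumes (converted with
    :func:`vertices_from_labels`) or ready-made vertex lists.  Unlinked
    detections that fail the division test simply start new tracks.
    """
    cfg = cfg or TrackingConfig()
    if len(frames) < 2:
        raise ValueError("tracking needs at least 2 frames")
    if frame_indices is None:
        frame_indices = list(range(len(frames)))
    vertex_frames: list[list[CellVertex]] = []
    for t, fr in zip(frame_indices, frames):
        if isinstance(fr, np.ndarray):
            vertex_frames.append(vertices_from_labels(fr, t, voxel_size))
        else:
            vertex_frames.append([
                v if v.frame == t else CellVertex(t, v.id, v.centroid, v.volume, v.length)
                for v in fr
            ])

    graph = LineageGraph()
    for vf in vertex_frames:
        for v in vf:
            graph.vertices[(v.frame, v.id)] = v

    for a_list, b_list in zip(vertex_frames[:-1], vertex_frames[1:]):
        if not a_list or not b_list:
            continue
        ta = a_list[0].frame
        tb = b_list[0].frame
        links = link_frames(a_list, b_list, cfg)
        linked_b = {b for _, b in links}
        unlinked_b = [v for v in b_list if v.id not in linked_b]
        parent_edges = detect_divisions(unlinked_b, links, a_list, cfg)
        dividing = {a for a, _ in parent_edges}
        for aid, bid in links:
            sem = PARENT if aid in dividing else TRACK
            graph.edges.append(LineageEdge((ta, aid), (tb, bid), sem))
        for aid, bid in parent_edges:
            graph.edges.append(LineageEdge((ta, aid), (tb, bid), PARENT))
    return graph


def relative_movement(gt_graph: LineageGraph) -> tuple[dict[int, float], float]:
    """Relative movement RM per frame and its overall mean.

    For each cell with a track edge from frame i to the next frame, RM is its
    own displacement divided by the distance to the closest detection in the
    next frame that is *not* its own successor.  Frames whose next frame has
    fewer than 2 detections are skipped with a warning.
    """
    frames = gt_graph.frames
    succ = {e.src: e.dst for e in gt_graph.edges if e.semantics == TRACK}
    per_frame: dict[int, float] = {}
    all_rm: list[float] = []
    for i, f in enumerate(frames[:-1]):
        f_next = frames[i + 1]
        next_vertices = gt_graph.frame_vertices(f_next)
        if len(next_vertices) < 2:
            warnings.warn(f"frame {f_next} has fewer than 2 cells; RM skipped",
                          stacklevel=2)
            continue
        rms = []
        for v in gt_graph.frame_vertices(f):
            key = (f, v.id)
            if key not in succ:
                continue
            s_key = succ[key]
            c = np.asarray(v.centroid)
            d_self = float(np.linalg.norm(c - gt_graph.vertices[s_key].centroid))
            d_others = [
                float(np.linalg.norm(c - np.asarray(w.centroid)))
                for w in next_vertices
                if (w.frame, w.id) != s_key
            ]
            if not d_others:
                continue
            d_min = min(d_others)
            if d_min > 0:
                rms.append(d_self / d_min)
        if rms:
            per_frame[f] = float(np.mean(rms))
            all_rm.extend(rms)
    mean = float(np.mean(all_rm)) if all_rm else float("nan")
    return per_frame, mean


def lineage_from_colony(
    frames: list[ColonyFrame],
    keep_every: int = 1,
) -> LineageGraph:
    """Ground-truth lineage graph of a simulated colony.

    With ``keep_every > 1`` the colony is temporally downsampled: a retained
    cell connects to its most recent retained ancestor; the edge is a track
    edge when the id is unchanged and a parent-daughter edge otherwise (the
    ancestor divided during the gap).
    """
    kept = frames[::keep_every]
    graph = LineageGraph()
    for fr in kept:
        for c in fr.cells:
            graph.vertices[(fr.t, c.id)] = CellVertex(
                fr.t, c.id, tuple(c.centroid), c.volume(), c.length
            )
    parent_of: dict[int, int | None] = {}
    for fr in frames:
        for c in fr.cells:
            parent_of.setdefault(c.id, c.parent_id)
    for prev, cur in zip(kept[:-1], kept[1:]):
        prev_ids = {c.id for c in prev.cells}
        for c in cur.cells:
            anc = c.id
            while anc is not None and anc not in prev_ids:
                anc = parent_of.get(anc)
            if anc is None:
                continue  # appeared without a retained ancestor
            sem = TRACK if anc == c.id else PARENT
            graph.edges.append(LineageEdge((prev.t, anc), (cur.t, c.id), sem))
    return graph
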