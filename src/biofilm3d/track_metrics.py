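"""Tracking evaluation with the AOGM (acyclic oriented graph matching) family.

The estimated lineage graph is compared with a reference graph through a
vertex correspondence (the detection test: an estimated object claims a
reference vertex when it covers more than half of its voxels).  Six graph
operations convert the estimated graph into the reference graph —

* vertex operations: NS (splits of falsely merged detections), FN (missing
  detections to add), FP (spurious detections to delete);
* edge operations: ED (delete), EA (add), EC (change track/parent-daughter
  semantics)

— and AOGM is their weighted sum.  TRA = 1 − min(AOGM, AOGM₀)/AOGM₀, where
AOGM₀ is the cost of building the reference graph from scratch.  ``TRA_edge``
uses edge operations only (normalized by the reference edge count);
``TRA_full`` weighs all six equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import LineageGraph, VertexKey

__all__ = [
    "AOGMWeights",
    "AOGMReport",
    "VertexCorrespondence",
    "match_vertices",
    "identity_correspondence",
    "aogm",
    "tra_scores",
    "EDGE_ONLY",
    "FULL_EQUAL",
]


@dataclass(frozen=True)
class AOGMWeights:
    w_NS: float = 1.0
    w_FN: float = 1.0
    w_FP: float = 1.0
    w_ED: float = 1.0
    w_EA: float = 1.0
    w_EC: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_NS, self.w_FN, self.w_FP, self.w_ED, self.w_EA, self.w_EC) < 0:
            raise ValueError("AOGM weights must be non-negative")


EDGE_ONLY = AOGMWeights(0.0, 0.0, 0.0, 1.0, 1.0, 1.0)
FULL_EQUAL = AOGMWeights(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


@dataclass
class VertexCorrespondence:
    """Mapping from reference vertices to the estimated vertices that detect them."""

    mapping: dict[VertexKey, VertexKey] = field(default_factory=dict)
    fn_vertices: list[VertexKey] = field(default_factory=list)
    fp_vertices: list[VertexKey] = field(default_factory=list)
    ns: int = 0

    @property
    def fn(self) -> int:
        return len(self.fn_vertices)

    @property
    def fp(self) -> int:
        return len(self.fp_vertices)


@dataclass
class AOGMReport:
    NS: int
    FN: int
    FP: int
    ED: int
    EA: int
    EC: int
    aogm: float
    aogm0: float
    tra: float

    def as_dict(self) -> dict[str, float]:
        return {
            "NS": self.NS, "FN": self.FN, "FP": self.FP,
            "ED": self.ED, "EA": self.EA, "EC": self.EC,
            "AOGM": self.aogm, "AOGM0": self.aogm0, "TRA": self.tra,
        }


def match_vertices(
    est_frames: list[np.ndarray],
    gt_frames: list[np.ndarray],
) -> VertexCorrespondence:
    """Per-frame detection test between estimated and reference label volumes.

    A reference object is detected by the estimated object covering more than
    half of its voxels (at most one such object exists).  An estimated object
    claimed by m ≥ 2 reference objects contributes m − 1 missed splits (NS);
    unclaimed estimated objects are FP, undetected reference objects FN.
    """
    if len(est_frames) != len(gt_frames):
        raise ValueError("frame count mismatch")
    corr = VertexCorrespondence()
    for t, (est, gt) in enumerate(zip(est_frames, gt_frames)):
        if est.shape != gt.shape:
            raise ValueError(f"frame {t}: shape mismatch {est.shape} vs {gt.shape}")
        gt_ids = np.unique(gt)
        gt_ids = gt_ids[gt_ids > 0]
        est_ids = np.unique(est)
        est_ids = est_ids[est_ids > 0]
        gt_sizes = np.bincount(gt.ravel())
        claimed: dict[int, int] = {}
        for g in gt_ids:
            overlap = est[gt == g]
            overlap = overlap[overlap > 0]
            if overlap.size == 0:
                corr.fn_vertices.append((t, int(g)))
                continue
            vals, counts = np.unique(overlap, return_counts=True)
            best = int(vals[np.argmax(counts)])
            if counts.max() * 2 > gt_sizes[g]:
                corr.mapping[(t, int(g))] = (t, best)
                claimed[best] = claimed.get(best, 0) + 1
            else:
                corr.fn_vertices.append((t, int(g)))
        corr.ns += sum(m - 1 for m in claimed.values() if m > 1)
        corr.fp_vertices.extend((t, int(e)) for e in est_ids if int(e) not in claimed)
    return corr


def identity_correspondence(est: LineageGraph, gt: LineageGraph) -> VertexCorrespondence:
    """Correspondence by vertex-key equality (shared detections, e.g. when
    both graphs were built on the same segmentation or on ground truth)."""
    corr = VertexCorrespondence()
    for key in gt.vertices:
        if key in est.vertices:
            corr.mapping[key] = key
        else:
            corr.fn_vertices.append(key)
    corr.fp_vertices = [k for k in est.vertices if k not in gt.vertices]
    return corr


def aogm(
    est: LineageGraph,
    gt: LineageGraph,
    correspondence: VertexCorrespondence,
    w: AOGMWeights = FULL_EQUAL,
) -> AOGMReport:
    """AOGM operation counts, weighted cost, and the TRA score.

    A reference edge has a counterpart when both its endpoints are detected
    and the corresponding estimated edge exists; counterparts with different
    semantics count as EC, reference edges without counterpart as EA, and
    estimated edges never used as a counterpart as ED.  AOGM₀ prices the
    reference graph built from an empty graph (one FN-weighted operation per
    vertex, one EA-weighted operation per edge).
    """
    if not gt.vertices:
        raise ValueError("AOGM0 undefined: empty reference graph")
    est_edges = est.edge_set()
    used: set[tuple[VertexKey, VertexKey]] = set()
    ea = ec = 0
    for e in gt.edges:
        src = correspondence.mapping.get(e.src)
        dst = correspondence.mapping.get(e.dst)
        if src is None or dst is None or src == dst or (src, dst) not in est_edges:
            ea += 1
            continue
        used.add((src, dst))
        if est_edges[(src, dst)] != e.semantics:
            ec += 1
    ed = sum(1 for k in est_edges if k not in used)
    ns, fn, fp = correspondence.ns, correspondence.fn, correspondence.fp
    cost = (w.w_NS * ns + w.w_FN * fn + w.w_FP * fp
            + w.w_ED * ed + w.w_EA * ea + w.w_EC * ec)
    aogm0 = w.w_FN * len(gt.vertices) + w.w_EA * len(gt.edges)
    if aogm0 == 0:
        raise ValueError("AOGM0 undefined: zero-cost reference graph under these weights")
    tra = 1.0 - min(cost, aogm0) / aogm0
    return AOGMReport(ns, fn, fp, ed, ea, ec, float(cost), float(aogm0), float(tra))


def tra_scores(
    est: LineageGraph,
    gt: LineageGraph,
    correspondence: VertexCorrespondence | None = None,
) -> tuple[float, float]:
    """(TRA_edge, TRA_full): edge-operations-only and all-six-operations TRA."""
    if correspondence is None:
        correspondence = identity_correspondence(est, gt)
    tra_edge = aogm(est, gt, correspondence, EDGE_ONLY).tra
    tra_full = aogm(est, gt, correspondence, FULL_EQUAL).tra
    return tra_edge, tra_full
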