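"""Segmentation quality metrics against reference labels.

Objects are matched one-to-one by greedy descending IoU above a threshold
(default 0.5, at which matches are mutually exclusive anyway); on the matched
pairs the module reports

* CA   — counting accuracy TP / (TP + FP + FN),
* SSA  — single-cell segmentation accuracy, the mean IoU of matched pairs,
* SBF1 — single-cell boundary F1 with a Euclidean distance tolerance
         (default √3 voxels) between boundary voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "MetricsConfig",
    "MatchResult",
    "match_objects",
    "counting_accuracy",
    "ssa",
    "sbf1",
    "pairwise_iou",
    "boundary_voxels",
    "evaluate_segmentation",
]


@dataclass(frozen=True)
class MetricsConfig:
    iou_threshold: float = 0.5
    sbf1_tolerance: float = float(np.sqrt(3.0))

    def __post_init__(self) -> None:
        if not 0 < self.iou_threshold <= 1:
            raise ValueError("iou_threshold must lie in (0, 1]")
        if self.sbf1_tolerance < 0:
            raise ValueError("sbf1_tolerance must be >= 0")


@dataclass
class MatchResult:
    """One-to-one object correspondence between predicted and reference labels."""

    pairs: list[tuple[int, int, float]]  # (pred id, ref id, IoU)
    unmatched_pred: list[int] = field(default_factory=list)  # false positives
    unmatched_ref: list[int] = field(default_factory=list)  # false negatives
    iou_threshold: float = 0.5

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_ref)


def pairwise_iou(pred: np.ndarray, ref: np.ndarray) -> dict[tuple[int, int], float]:
    """IoU of every overlapping (pred, ref) object pair."""
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    p = pred.ravel()
    r = ref.ravel()
    both = (p > 0) & (r > 0)
    if not both.any():
        return {}
    pair_codes, inter = np.unique(
        p[both].astype(np.int64) * (np.int64(r.max()) + 1) + r[both], return_counts=True
    )
    p_sizes = np.bincount(p)
    r_sizes = np.bincount(r)
    out: dict[tuple[int, int], float] = {}
    mod = np.int64(r.max()) + 1
    for code, n_int in zip(pair_codes, inter):
        pid = int(code // mod)
        rid = int(code % mod)
        union = p_sizes[pid] + r_sizes[rid] - n_int
        out[(pid, rid)] = float(n_int / union)
    return out


def match_objects(pred: np.ndarray, ref: np.ndarray,
                  cfg: MetricsConfig | None = None) -> MatchResult:
    """Greedy IoU-descending one-to-one matching above the IoU threshold.

    Candidate pairs are sorted by decreasing IoU (ties broken by smaller pred
    id, then ref id) and accepted while both objects are unused; leftover
    predicted objects are false positives, leftover reference objects false
    negatives.
    """
    cfg = cfg or MetricsConfig()
    ious = pairwise_iou(pred, ref)
    candidates = sorted(ious.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    used_p: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for (pid, rid), iou in candidates:
        if iou < cfg.iou_threshold:
            break
        if pid in used_p or rid in used_r:
            continue
        pairs.append((pid, rid, iou))
        used_p.add(pid)
        used_r.add(rid)
    pred_ids = np.unique(pred)
    ref_ids = np.unique(ref)
    return MatchResult(
        pairs=pairs,
        unmatched_pred=[int(i) for i in pred_ids if i > 0 and i not in used_p],
        unmatched_ref=[int(i) for i in ref_ids if i > 0 and i not in used_r],
        iou_threshold=cfg.iou_threshold,
    )


def counting_accuracy(m: MatchResult) -> float:
    """CA = TP / (TP + FP + FN); undefined (error) when no objects exist at all."""
    denom = m.tp + m.fp + m.fn
    if denom == 0:
        raise ValueError("undefined CA: no objects in either volume")
    return m.tp / denom


def ssa(m: MatchResult) -> float:
    """Mean IoU over matched pairs."""
    if not m.pairs:
        raise ValueError("SSA undefined: no matched pairs")
    return float(np.mean([iou for _, _, iou in m.pairs]))


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (n, ndim) of object voxels with a non-object face neighbour.

    6-connectivity; neighbours are only looked up inside the array, so a
    singleton axis (a single-slice volume) contributes no exterior — the 2D
    boundary of an embedded slice comes out as expected.
    """
    interior = np.ones_like(mask)
    for ax in range(mask.ndim):
        if mask.shape[ax] == 1:
            continue
        lo = np.ones_like(mask)
        hi = np.ones_like(mask)
        sl_to = [slice(None)] * mask.ndim
        sl_from = [slice(None)] * mask.ndim
        sl_to[ax] = slice(1, None)
        sl_from[ax] = slice(None, -1)
        lo[tuple(sl_to)] = mask[tuple(sl_from)]
        hi[tuple(sl_from)] = mask[tuple(sl_to)]
        interior &= lo & hi
    return np.argwhere(mask & ~interior)


def _boundary_f1(pred_mask: np.ndarray, ref_mask: np.ndarray, tol: float) -> float:
    pb = boundary_voxels(pred_mask)
    rb = boundary_voxels(ref_mask)
    if len(pb) == 0 or len(rb) == 0:
        return 0.0
    dist_p = cKDTree(rb).query(pb, k=1)[0]
    dist_r = cKDTree(pb).query(rb, k=1)[0]
    precision = float(np.mean(dist_p <= tol + 1e-9))
    recall = float(np.mean(dist_r <= tol + 1e-9))
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def sbf1(pred: np.ndarray, ref: np.ndarray, m: MatchResult,
         cfg: MetricsConfig | None = None) -> float:
    """Single-cell boundary F1 averaged over matched pairs.

    Per pair: precision is the fraction of predicted boundary voxels within
    the distance tolerance of any reference boundary voxel, recall the
    symmetric fraction, combined as 2PR/(P+R).
    """
    cfg = cfg or MetricsConfig()
    if not m.pairs:
        raise ValueError("SBF1 undefined: no matched pairs")
    objects_p = ndimage.find_objects(pred)
    objects_r = ndimage.find_objects(ref)
    scores = []
    for pid, rid, _ in m.pairs:
        sp, sr = objects_p[pid - 1], objects_r[rid - 1]
        # one-voxel pad so object surfaces at the crop edge stay detectable
        joint = tuple(
            slice(max(min(a.start, b.start) - 1, 0), min(max(a.stop, b.stop) + 1, dim))
            for a, b, dim in zip(sp, sr, pred.shape)
        )
        scores.append(
            _boundary_f1(pred[joint] == pid, ref[joint] == rid, cfg.sbf1_tolerance)
        )
    return float(np.mean(scores))


def evaluate_segmentation(pred: np.ndarray, ref: np.ndarray,
                          cfg: MetricsConfig | None = None) -> dict[str, float]:
    """CA/SSA/SBF1 summary for one predicted volume against its reference."""
    cfg = cfg or MetricsConfig()
    m = match_objects(pred, ref, cfg)
    out: dict[str, float] = {
        "iou_threshold": cfg.iou_threshold,
        "TP": m.tp,
        "FP": m.fp,
        "FN": m.fn,
        "CA": counting_accuracy(m),
    }
    out["SSA"] = ssa(m) if m.pairs else float("nan")
    out["SBF1"] = sbf1(pred, ref, m, cfg) if m.pairs else float("nan")
    return out
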