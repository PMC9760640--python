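"""Intermediate image representations computed from ground-truth label volumes.

Two deterministic transforms of an instance label volume serve both as
training targets for an image-to-image network and as the inputs to the
watershed post-processing:

* the *distance-to-nearest-cell-exterior* map D — the per-cell normalized
  Euclidean distance transform raised to a power (default 3) so intensity
  peaks sharply at cell centres, then Gaussian-blurred;
* the *proximity-enhanced cell boundary* map B — (binary − normalized
  distance) times the capped inverse distance to the nearest *other* cell,
  hole-filled by grayscale closing, then Gaussian-blurred.  B traces every
  cell's boundary and is brightest where two cells nearly touch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ReprConfig",
    "RepresentationPair",
    "distance_to_exterior",
    "proximity_boundary",
    "make_training_pair",
    "raw_cell_distances",
    "normalized_cell_distances",
]


@dataclass(frozen=True)
class ReprConfig:
    """Parameters of the representation transforms.

    ``blur_kernel`` is the Gaussian window size in voxels per axis (odd); the
    sigma is 1 voxel, truncated to that window.  ``distance_power`` sharpens
    the distance map (cubing by default).  ``inverse_cap`` bounds the inverse
    distance to other cells (adjacent voxels are 1 voxel apart, so 1/dist ≤ 1).
    """

    distance_power: int = 3
    blur_kernel: int = 5
    closing_radius: int = 1
    inverse_cap: float = 1.0
    sampling: tuple[float, float, float] | None = None  # per-axis voxel weights
    #: other-cell distances beyond this many voxels contribute 0 to the
    #: boundary map (the capped inverse 1/d is below 1/range there)
    other_distance_range: int = 32

    def __post_init__(self) -> None:
        if self.distance_power < 1:
            raise ValueError("distance_power must be >= 1")
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ValueError("blur_kernel must be odd and >= 1")

    def blur(self, volume: np.ndarray) -> np.ndarray:
        """Gaussian blur with σ = 1 voxel truncated to the configured window."""
        if self.blur_kernel == 1:
            return volume
        radius = (self.blur_kernel - 1) // 2
        return ndimage.gaussian_filter(volume, sigma=1.0, truncate=float(radius))


@dataclass
class RepresentationPair:
    """The two intermediate volumes computed from one label volume."""

    dist_rep: np.ndarray
    boundary_rep: np.ndarray

    @property
    def source_shape(self) -> tuple[int, ...]:
        return self.dist_rep.shape

    def __post_init__(self) -> None:
        if self.dist_rep.shape != self.boundary_rep.shape:
            raise ValueError("representation volumes must share a shape")


def _iter_cells(labels: np.ndarray):
    """Yield (id, full-volume slice expanded by 1, local mask) per cell."""
    objects = ndimage.find_objects(labels)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        grown = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, labels.shape)
        )
        yield k, grown, labels[grown] == k


def raw_cell_distances(labels: np.ndarray, cfg: ReprConfig | None = None) -> np.ndarray:
    """Per-cell Euclidean distance to the nearest voxel outside that cell.

    Distances are voxel-centre to voxel-centre, in voxel units (or weighted
    by ``cfg.sampling``); background is 0.
    """
    cfg = cfg or ReprConfig()
    out = np.zeros(labels.shape, dtype=np.float64)
    for _, sl, mask in _iter_cells(labels):
        raw = ndimage.distance_transform_edt(mask, sampling=cfg.sampling)
        out[sl] = np.where(mask, raw, out[sl])
    return out


def normalized_cell_distances(labels: np.ndarray, cfg: ReprConfig) -> np.ndarray:
    """Per-cell distances of :func:`raw_cell_distances` normalized to each
    cell's own maximum (so every cell peaks at exactly 1)."""
    out = raw_cell_distances(labels, cfg)
    objects = ndimage.find_objects(labels)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = labels[sl] == k
        m = out[sl][mask].max() if mask.any() else 0.0
        if m > 0:
            out[sl] = np.where(mask, out[sl] / m, out[sl])
        else:  # single-voxel cell: its only voxel is its own maximum
            out[sl] = np.where(mask, 1.0, out[sl])
    return out


def distance_to_exterior(labels: np.ndarray, cfg: ReprConfig | None = None,
                         blur: bool = True) -> np.ndarray:
    """Distance-to-nearest-cell-exterior representation D.

    Normalized per-cell EDT raised to ``cfg.distance_power``, then Gaussian
    blurred (set ``blur=False`` for the pre-blur map used by tests/oracles).
    """
    cfg = cfg or ReprConfig()
    rep = normalized_cell_distances(labels, cfg) ** cfg.distance_power
    return cfg.blur(rep) if blur else rep


def proximity_boundary(labels: np.ndarray, cfg: ReprConfig | None = None,
                       blur: bool = True) -> np.ndarray:
    """Proximity-enhanced cell boundary representation B.

    A = binary map − normalized distances (pre-power): a shell that rises
    toward each cell's own boundary.  C = capped inverse Euclidean distance
    to the nearest voxel of a *different* cell (0 outside cells; 0 when no
    other cell exists).  The product A·C is hole-filled by grayscale closing
    and Gaussian blurred.
    """
    cfg = cfg or ReprConfig()
    binary = labels > 0
    a_map = np.where(binary, 1.0 - normalized_cell_distances(labels, cfg), 0.0)

    c_map = np.zeros(labels.shape, dtype=np.float64)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size >= 2:
        objects = ndimage.find_objects(labels)
        for k in ids:
            sl = objects[int(k) - 1]
            inv = _inverse_other_distance(labels, sl, int(k), cfg)
            mask = labels[sl] == k
            c_map[sl] = np.where(mask, inv, c_map[sl])

    out = a_map * c_map
    if cfg.closing_radius > 0:
        size = 2 * cfg.closing_radius + 1
        out = ndimage.grey_closing(out, size=(size, size, size))
    return cfg.blur(out) if blur else out


def _inverse_other_distance(labels: np.ndarray, sl: tuple[slice, ...], k: int,
                            cfg: ReprConfig) -> np.ndarray:
    """Capped inverse distance from cell k's bbox voxels to the nearest
    voxel of a different cell.

    Evaluated in a window around the cell that grows (4, 8, 16, … voxels)
    until every distance is confirmed exact or exceeds
    ``cfg.other_distance_range`` — beyond which the capped inverse is below
    ``1/range`` and treated as 0.
    """
    min_sampling = 1.0 if cfg.sampling is None else float(min(cfg.sampling))
    margin = 4
    while True:
        win = tuple(
            slice(max(s.start - margin, 0), min(s.stop + margin, dim))
            for s, dim in zip(sl, labels.shape)
        )
        sub = labels[win]
        others = (sub > 0) & (sub != k)
        if not others.any():
            dist = np.full(sub.shape, np.inf)
        else:
            dist = ndimage.distance_transform_edt(~others, sampling=cfg.sampling)
        local = tuple(
            slice(s.start - w.start, s.stop - w.start) for s, w in zip(sl, win)
        )
        out = dist[local]
        cell_dist = out[labels[sl] == k]
        # a windowed distance below the margin is exact (the nearest other
        # voxel provably lies inside the window)
        exact_cut = margin * min_sampling
        if margin >= cfg.other_distance_range or (
            cell_dist.size == 0 or cell_dist.max() < exact_cut
        ):
            inv = np.where(
                out < exact_cut,
                np.minimum(cfg.inverse_cap, 1.0 / np.maximum(out, 1e-12)),
                0.0,
            )
            return inv
        margin *= 2


def make_training_pair(labels: np.ndarray, cfg: ReprConfig | None = None) -> RepresentationPair:
    """Both representations computed consistently from the same labels."""
    cfg = cfg or ReprConfig()
    return RepresentationPair(
        dist_rep=distance_to_exterior(labels, cfg),
        boundary_rep=proximity_boundary(labels, cfg),
    )
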