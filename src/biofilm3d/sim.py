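"""Synthetic biofilm generator: rod-shaped cell colonies and fluorescence rendering.

Cells are spherocylinders (cylinder of diameter ``d`` with hemispherical caps,
tip-to-tip length ``l``).  A minimal individual-based model grows and divides
cells, a pairwise push-apart relaxation enforces a minimum-separation
criterion, and a renderer turns voxelized label masks into realistic 3D
fluorescence images (randomly placed fluorophores convolved with a PSF, plus
Poisson shot noise and Gaussian read noise).

All volumes are ZYX-ordered; physical coordinates are in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

__all__ = [
    "SimCellState",
    "ColonyFrame",
    "RenderConfig",
    "DensityReport",
    "grow_colony",
    "voxelize",
    "render",
    "estimate_sbr",
    "solve_photons_for_sbr",
    "local_density",
    "colony_bounding_shape",
]

#: fraction of the diameter by which two cells may interpenetrate after relaxation
OVERLAP_TOL_FRACTION = 0.05


@dataclass
class SimCellState:
    """State of a single rod-shaped (spherocylindrical) cell.

    ``centroid`` and ``axis`` are ZYX 3-vectors in µm; ``length`` is the
    tip-to-tip length so ``length == diameter`` degenerates to a sphere.
    """

    id: int
    parent_id: int | None
    centroid: np.ndarray
    axis: np.ndarray
    length: float
    diameter: float
    growth_rate: float

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        norm = float(np.linalg.norm(self.axis))
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("cell axis must be a nonzero vector")
            self.axis = self.axis / norm
        if self.length < self.diameter - 1e-12:
            raise ValueError(
                f"cell {self.id}: length {self.length} < diameter {self.diameter}"
            )

    @property
    def half_segment(self) -> float:
        """Half-length of the centreline segment (excludes the caps)."""
        return max(self.length - self.diameter, 0.0) / 2.0

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of the spherocylinder centreline segment."""
        h = self.half_segment
        return self.centroid - h * self.axis, self.centroid + h * self.axis

    def volume(self) -> float:
        """Analytic spherocylinder volume in µm³."""
        r = self.diameter / 2.0
        return np.pi * r * r * (self.length - self.diameter) + 4.0 / 3.0 * np.pi * r**3


@dataclass
class ColonyFrame:
    """All cells present at one time step."""

    t: int
    cells: list[SimCellState] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError(f"frame {self.t}: duplicate cell ids")


@dataclass
class RenderConfig:
    """Parameters of the fluorescence image formation model.

    ``psf`` may be a 3D kernel volume (must sum to 1), a 3-tuple of Gaussian
    sigmas in µm (ZYX), or None for the default anisotropic Gaussian
    (σ_xy = 0.1 µm, σ_z = 2.5 σ_xy — light-sheet PSFs are elongated axially).
    ``read_noise`` defaults to 3.04 photons RMS, a typical calibrated
    sCMOS detector value.
    """

    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    psf: np.ndarray | tuple[float, float, float] | None = None
    labeling_mode: str = "cytosolic"
    fluorophores_per_cell: int = 500
    photons_per_fluorophore: float = 50.0
    background_mean: float = 100.0
    read_noise: float = 3.04
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.labeling_mode not in ("cytosolic", "membrane"):
            raise ValueError(f"unknown labeling_mode {self.labeling_mode!r}")
        if self.read_noise < 0:
            raise ValueError("read_noise must be >= 0")
        if isinstance(self.psf, np.ndarray):
            if np.any(self.psf < 0) or not np.isclose(self.psf.sum(), 1.0, atol=1e-6):
                raise ValueError("PSF kernel must be non-negative and sum to 1")

    def psf_sigmas_voxels(self) -> tuple[float, float, float] | None:
        """Gaussian sigmas in voxel units, or None when a measured kernel is set."""
        if isinstance(self.psf, np.ndarray):
            return None
        if self.psf is None:
            sxy = 0.1
            sig_um = (2.5 * sxy, sxy, sxy)
        else:
            sig_um = self.psf
        return tuple(s / v for s, v in zip(sig_um, self.voxel_size))


@dataclass
class DensityReport:
    """Local cell-density estimate from the densest 3D tiles."""

    tile_shape: tuple[int, int, int]
    per_tile_density: list[float]
    reported_density: float


# ---------------------------------------------------------------------------
# colony growth
# ---------------------------------------------------------------------------


def _segment_pair_closest(p1, q1, p2, q2):
    """Vectorized closest points between segment pairs (p1,q1) and (p2,q2).

    Arrays of shape (n, 3). Returns (c1, c2, dist). Handles degenerate
    (zero-length) segments.
    """
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)

    eps = 1e-14
    denom = a * e - b * b
    s = np.where(denom > eps, np.clip((b * f - c * e) / np.where(denom > eps, denom, 1.0), 0, 1), 0.0)
    e_safe = np.where(e > eps, e, 1.0)
    t = (b * s + f) / e_safe
    t_low = t < 0
    t_high = t > 1
    a_safe = np.where(a > eps, a, 1.0)
    s = np.where(t_low, np.clip(-c / a_safe, 0, 1), s)
    s = np.where(t_high, np.clip((b - c) / a_safe, 0, 1), s)
    t = np.clip(t, 0, 1)
    t = np.where(e <= eps, 0.0, t)
    s = np.where(a <= eps, 0.0, s)
    c1 = p1 + d1 * s[:, None]
    c2 = p2 + d2 * t[:, None]
    dist = np.linalg.norm(c1 - c2, axis=1)
    return c1, c2, dist


def _relax(cells: list[SimCellState], d: float, rng: np.random.Generator,
           max_iter: int = 500, frame: int = 0) -> None:
    """Iterative pairwise push-apart until the minimum-separation criterion holds.

    Two cells violate it when their centreline segments are closer than
    ``d - overlap_tol`` (overlap_tol = 5% of the diameter): residual slight
    contact is tolerated, mimicking collision *alleviation* rather than
    strict exclusion.
    """
    n = len(cells)
    if n < 2:
        return
    min_sep = d * (1.0 - OVERLAP_TOL_FRACTION)
    ii, jj = np.triu_indices(n, k=1)
    for _ in range(max_iter):
        ends = [c.endpoints() for c in cells]
        p = np.array([e[0] for e in ends])
        q = np.array([e[1] for e in ends])
        c1, c2, dist = _segment_pair_closest(p[ii], q[ii], p[jj], q[jj])
        deficit = min_sep - dist
        bad = deficit > 1e-9
        if not bad.any():
            return
        disp = np.zeros((n, 3))
        u = c1[bad] - c2[bad]
        dn = dist[bad]
        zero = dn < 1e-12
        if zero.any():
            u[zero] = rng.normal(size=(int(zero.sum()), 3))
            dn = np.where(zero, np.linalg.norm(u, axis=1), dn)
        u = u / dn[:, None]
        push = 0.55 * deficit[bad][:, None] * u  # slight over-relaxation
        np.add.at(disp, ii[bad], push)
        np.add.at(disp, jj[bad], -push)
        for k in range(n):
            cells[k].centroid = cells[k].centroid + disp[k]
    raise RuntimeError(f"relaxation failed to resolve overlaps at frame {frame}")


def _random_perpendicular_tilt(axis: np.ndarray, angle: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Rotate a unit vector by `angle` radians about a random perpendicular axis."""
    v = rng.normal(size=3)
    v -= axis * np.dot(v, axis)
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        return axis.copy()
    v /= nv
    out = np.cos(angle) * axis + np.sin(angle) * v
    return out / np.linalg.norm(out)


def grow_colony(
    n_steps: int,
    d: float = 0.6,
    l_div: float = 2.0,
    n_seed_cells: int = 1,
    rng_seed: int = 0,
    growth_rate: float = 0.1,
    seed_region: float | None = None,
) -> list[ColonyFrame]:
    """Grow a rod-shaped cell colony with division and collision relaxation.

    Cells elongate at a constant per-cell rate (``growth_rate`` µm/step with a
    ±10% per-cell jitter fixed at birth).  When a cell's tip-to-tip length
    exceeds ``l_div`` it divides into two daughters of half length, placed end
    to end along the parent axis with a small (5°) random reorientation;
    daughters record the parent id.  After growth and division a minimum
    distance criterion between all cell pairs is enforced by iterative
    push-apart relaxation.

    Returns ``n_steps + 1`` frames; frame 0 is the relaxed seed configuration.
    Deterministic for a fixed ``rng_seed``.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if d <= 0 or l_div <= d:
        raise ValueError("require d > 0 and l_div > d")
    rng = np.random.default_rng(rng_seed)
    if seed_region is None:
        seed_region = max(l_div, d * n_seed_cells ** (1 / 3) * 2.0)

    def jittered_rate() -> float:
        return growth_rate * (1.0 + 0.1 * rng.uniform(-1, 1))

    next_id = 1
    cells: list[SimCellState] = []
    for _ in range(n_seed_cells):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        length = rng.uniform(0.55, 0.8) * l_div
        centroid = rng.uniform(-seed_region / 2, seed_region / 2, size=3)
        cells.append(
            SimCellState(next_id, None, centroid, axis, max(length, d), d, jittered_rate())
        )
        next_id += 1
    _relax(cells, d, rng, frame=0)
    frames = [ColonyFrame(0, [replace(c, centroid=c.centroid.copy(), axis=c.axis.copy()) for c in cells])]

    tilt = np.deg2rad(5.0)
    for t in range(1, n_steps + 1):
        grown: list[SimCellState] = []
        for c in cells:
            c.length += c.growth_rate
            if c.length > l_div:
                half = c.length / 2.0
                offset = c.length / 4.0
                for sgn in (-1.0, 1.0):
                    ax = _random_perpendicular_tilt(c.axis, tilt, rng)
                    grown.append(
                        SimCellState(
                            next_id, c.id,
                            c.centroid + sgn * offset * c.axis,
                            ax, max(half, c.diameter), c.diameter, jittered_rate(),
                        )
                    )
                    next_id += 1
            else:
                grown.append(c)
        cells = grown
        _relax(cells, d, rng, frame=t)
        frames.append(
            ColonyFrame(t, [replace(c, centroid=c.centroid.copy(), axis=c.axis.copy()) for c in cells])
        )
    return frames


def colony_bounding_shape(
    cells: list[SimCellState],
    voxel_size: tuple[float, float, float],
    pad_um: float = 0.5,
) -> tuple[tuple[int, int, int], np.ndarray]:
    """Voxel-grid shape and physical origin that contain all cells with padding.

    Returns ``(shape_zyx, origin_um)``; pass ``origin`` to :func:`voxelize` so
    that the colony sits inside the volume.
    """
    if not cells:
        raise ValueError("no cells")
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for c in cells:
        reach = c.length / 2.0
        lo = np.minimum(lo, c.centroid - reach)
        hi = np.maximum(hi, c.centroid + reach)
    lo -= pad_um
    hi += pad_um
    vs = np.asarray(voxel_size, float)
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / vs[i])) for i in range(3))
    return shape, lo


def voxelize(
    cells: list[SimCellState],
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1),
    origin: np.ndarray | None = None,
) -> np.ndarray:
    """Rasterize spherocylinders into an integer label volume (ZYX).

    A voxel gets label ``k`` iff its centre lies inside cell ``k``; where
    residual overlaps remain, the closer cell axis wins, then the smaller id.
    Cells extending past the volume bounds are clipped with a warning.
    """
    labels = np.zeros(shape, dtype=np.int32)
    if not cells:
        return labels
    vs = np.asarray(voxel_size, float)
    org = np.zeros(3) if origin is None else np.asarray(origin, float)
    best = np.full(shape, np.inf, dtype=np.float64)
    extent = np.asarray(shape) * vs + org

    for cell in sorted(cells, key=lambda c: c.id):
        r = cell.diameter / 2.0
        reach = cell.length / 2.0 + vs.max()
        lo_phys = cell.centroid - reach
        hi_phys = cell.centroid + reach
        if np.any(lo_phys < org - 1e-9) or np.any(hi_phys > extent + 1e-9):
            warnings.warn(f"cell {cell.id} clipped at volume edge", stacklevel=2)
        lo = np.maximum(np.floor((lo_phys - org) / vs).astype(int), 0)
        hi = np.minimum(np.ceil((hi_phys - org) / vs).astype(int), shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.meshgrid(
            *(org[i] + (np.arange(lo[i], hi[i]) + 0.5) * vs[i] for i in range(3)),
            indexing="ij",
        )
        pts = np.stack([zz, yy, xx], axis=-1)
        p, q = cell.endpoints()
        seg = q - p
        seg_len2 = float(np.dot(seg, seg))
        if seg_len2 < 1e-18:
            dist = np.linalg.norm(pts - cell.centroid, axis=-1)
        else:
            tt = np.clip(np.einsum("...i,i->...", pts - p, seg) / seg_len2, 0, 1)
            closest = p + tt[..., None] * seg
            dist = np.linalg.norm(pts - closest, axis=-1)
        sl = tuple(slice(lo[i], hi[i]) for i in range(3))
        inside = (dist <= r) & (dist < best[sl])
        best[sl] = np.where(inside, dist, best[sl])
        labels[sl] = np.where(inside, cell.id, labels[sl])
    return labels


# ---------------------------------------------------------------------------
# image formation
# ---------------------------------------------------------------------------


def _membrane_shell(mask: np.ndarray) -> np.ndarray:
    """One-voxel-thick surface shell of a binary mask (6-connectivity)."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return mask & ~eroded


def _emitter_field(labels: np.ndarray, cfg: RenderConfig, rng: np.random.Generator) -> np.ndarray:
    """Photon-emission field: fluorophores placed uniformly per cell."""
    field_vol = np.zeros(labels.shape, dtype=np.float64)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    objects = ndimage.find_objects(labels)
    for k in ids:
        sl = objects[int(k) - 1]
        mask = labels[sl] == k
        if cfg.labeling_mode == "membrane":
            mask = _membrane_shell(mask)
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            continue
        chosen = rng.choice(idx, size=cfg.fluorophores_per_cell, replace=True)
        counts = np.bincount(chosen, minlength=mask.size).reshape(mask.shape)
        field_vol[sl] += counts * cfg.photons_per_fluorophore
    return field_vol


def _noiseless_image(labels: np.ndarray, cfg: RenderConfig, rng: np.random.Generator) -> np.ndarray:
    field_vol = _emitter_field(labels, cfg, rng)
    if isinstance(cfg.psf, np.ndarray):
        blurred = fftconvolve(field_vol, cfg.psf, mode="same")
        blurred = np.clip(blurred, 0, None)
    else:
        blurred = ndimage.gaussian_filter(field_vol, sigma=cfg.psf_sigmas_voxels())
    return blurred + cfg.background_mean


def render(labels: np.ndarray, cells: list[SimCellState] | None, cfg: RenderConfig) -> np.ndarray:
    """Render a 3D fluorescence image from a label volume.

    Fluorophores are sampled uniformly over each cell's voxels (cytosolic
    mode) or over a one-voxel surface shell (membrane mode), scaled by the
    photon budget, convolved with the PSF, offset by the mean background, and
    corrupted with Poisson shot noise plus Gaussian read noise (clipped at 0).
    The input label volume is never modified.  Deterministic for a fixed
    ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    noiseless = _noiseless_image(labels, cfg, rng)
    image = rng.poisson(noiseless).astype(np.float64)
    if cfg.read_noise > 0:
        image += rng.normal(0.0, cfg.read_noise, size=image.shape)
    return np.clip(image, 0.0, None)


def estimate_sbr(image: np.ndarray, labels: np.ndarray, shell: int = 5) -> float:
    """Signal-to-background ratio: mean foreground over mean near-cell background.

    Background voxels are those within ``shell`` voxels (Euclidean) of any
    cell, emulating manually chosen background regions close to the cells.
    """
    fg = labels > 0
    if not fg.any():
        raise ValueError("labels contain no cells")
    dist_to_cell = ndimage.distance_transform_edt(~fg)
    bg = (~fg) & (dist_to_cell <= shell)
    if not bg.any():
        raise ValueError("empty background shell")
    return float(image[fg].mean() / image[bg].mean())


def solve_photons_for_sbr(
    labels: np.ndarray,
    cfg: RenderConfig,
    target_sbr: float,
    shell: int = 5,
    tol: float = 1e-3,
    max_iter: int = 60,
) -> float:
    """Photon budget per fluorophore that yields ``target_sbr`` in expectation.

    Bisection on ``photons_per_fluorophore`` against the SBR of the noiseless
    expected image (the SBR is monotone in the photon budget).
    """
    if target_sbr <= 1.0:
        raise ValueError("target SBR must exceed 1")
    rng = np.random.default_rng(cfg.rng_seed)
    unit_cfg = replace(cfg, photons_per_fluorophore=1.0)
    unit_signal = _noiseless_image(labels, unit_cfg, rng) - cfg.background_mean

    def sbr_at(p: float) -> float:
        img = unit_signal * p + cfg.background_mean
        return estimate_sbr(img, labels, shell)

    lo, hi = 0.0, 1.0
    while sbr_at(hi) < target_sbr:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("cannot reach target SBR: no signal in foreground")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if sbr_at(mid) < target_sbr:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


def local_density(labels: np.ndarray, tile_shape: tuple[int, int, int] = (8, 64, 64)) -> DensityReport:
    """Local cell density from 3D tiles (default 64×64×8 voxels, stored ZYX).

    The volume is partitioned into tiles (partial edge tiles dropped), each
    tile's foreground fraction is computed, and the reported density is the
    mean of the 10 densest tiles (or all tiles if fewer).
    """
    tz, ty, tx = tile_shape
    nz, ny, nx = (s // t for s, t in zip(labels.shape, tile_shape))
    if nz < 1 or ny < 1 or nx < 1:
        raise ValueError(f"volume {labels.shape} smaller than one tile {tile_shape}")
    fg = (labels[: nz * tz, : ny * ty, : nx * tx] > 0).astype(np.float64)
    tiles = fg.reshape(nz, tz, ny, ty, nx, tx).mean(axis=(1, 3, 5)).ravel()
    top = np.sort(tiles)[::-1][:10]
    return DensityReport(tuple(tile_shape), tiles.tolist(), float(top.mean()))
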