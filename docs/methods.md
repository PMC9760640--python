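# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `biofilm3d`, module by module.

## Synthetic biofilm generator (`biofilm3d.sim`)

**Cell geometry.** Cells are spherocylinders with diameter `d` and
tip-to-tip length `l` (`l = d` degenerates to a sphere). Defaults follow the
two species the pipeline targets: *E. coli*-like (`d = 1 µm`,
division length `l_div = 3 µm`) and *S. oneidensis*-like (`d = 0.6 µm`,
`l_div = 2 µm`).

**Growth model.** A deliberately minimal individual-based model stands in
for a full biomechanical simulator: colony geometry is all the downstream
pipeline consumes, so any generator of overlap-free rod packings with
lineage bookkeeping suffices. Per step each cell elongates at a constant
rate (default 0.1–0.15 µm/step with a ±10% per-cell jitter fixed at birth).
A cell crossing `l_div` divides into two half-length daughters placed end to
end along the parent axis, each tilted by 5° about a random perpendicular
axis; daughters record `parent_id`, the parent vanishes. After growth and
division, a minimum-distance criterion is enforced by iterative pairwise
push-apart: whenever two centreline segments come closer than
`d · (1 − 0.05)`, both cells are displaced apart along the closest-point
vector (slight over-relaxation, factor 0.55) until no violation remains
(error after 500 sweeps). The 5% overlap tolerance reflects that collisions
are *alleviated*, not strictly excluded, in crowded colonies. Everything is
driven by one `numpy` generator seed; runs are bit-reproducible.

**Voxelization.** A voxel belongs to cell *k* iff its centre lies inside
*k*'s spherocylinder; residual overlap ties go to the closer axis, then the
smaller id. The voxel-centre rule is unbiased for generic poses; axes
aligned with the grid can bias the voxel count by >10% at `r = 3` voxels
(tests use grid-incommensurate poses). Volumes are ZYX, physical units µm.

**Image formation.** Fluorophores (default 500/cell) are placed uniformly
over the cell's voxels (cytosolic mode) or over a one-voxel surface shell
(membrane mode — thinner shells are not resolvable at these voxel sizes).
The emitter field is scaled by the photon budget, convolved with the PSF,
offset by the mean background, then corrupted by Poisson shot noise on the
summed signal-plus-background and additive Gaussian read noise (default
3.04 photons RMS, a typical calibrated sCMOS figure), clipped at zero. When
no measured PSF volume is supplied, an anisotropic Gaussian is used
(σ_xy = 0.1 µm, σ_z = 2.5 σ_xy; light-sheet PSFs are elongated axially).
The photon budget needed to reach a requested SBR is solved by bisection on
the noiseless expected image (SBR is monotone in the budget).

**SBR and density.** SBR = mean foreground intensity over mean intensity of
background voxels within 5 voxels of any cell (near-cell background, as a
human annotator would choose). Local density partitions the volume into
64×64×8-voxel tiles (ZYX storage (8, 64, 64)), drops partial edge tiles, and
reports the mean foreground fraction of the 10 densest tiles.

**What the generator does not emulate.** Optical aberrations, spatially
varying background, cell motility, dispersal/attachment dynamics, curved or
aberrant cell shapes, and extracellular matrix. Passing tests demonstrate
correctness of the pipeline's algorithms under controlled geometry and
noise; they do not certify performance on experimental stacks.

## Intermediate representations (`biofilm3d.representations`)

Distances are Euclidean, voxel-centre to voxel-centre, computed per cell on
a one-voxel-grown bounding box (exact: the nearest exterior voxel of any
in-cell voxel provably lies inside that window). Isotropic voxels are
assumed; `ReprConfig.sampling` supplies per-axis weights otherwise.

- `D`: per-cell EDT normalized to the cell max, raised to
  `distance_power = 3`, blurred with a Gaussian of σ = 1 voxel truncated to
  the 5-voxel kernel window. The power sharpens the core without moving the
  per-cell argmax.
- `B`: `(binary − normalized distance)` — the normalization uses the
  *pre-power* distances — multiplied by the capped inverse distance to the
  nearest different-label voxel, hole-filled by grayscale closing
  (3×3×3 by default), then blurred. With the cap at 1, adjacent voxels
  contribute 1 and isolated cells get vanishing boundaries; no per-cell
  rescaling is applied (the literal product), so `B` is a *proximity*
  map first and an outline second.

The inverse-distance factor is evaluated in an adaptively grown window
around each cell (margins 4, 8, 16, … voxels). A windowed distance below
the margin is provably exact; distances beyond `other_distance_range`
(default 32 voxels, where the capped inverse is < 1/32) are treated as
zero. This keeps the computation `O(cells · window)` instead of
`O(cells · volume)` with an error bounded by `1/other_distance_range` in
regions that contribute essentially nothing to the boundary map.

## Segmentation (`biofilm3d.segmentation`)

The predictor contract is any `image → (D, B)` map of identical shape. The
oracle predictor emits the exact representations of a known label volume and
exists so that every post-processing stage, metric, and the tracking chain
can be validated independently of network training. A trainable backend
would slot behind the same contract; none ships with the package, and the
post-processing clips negative predictor outputs at zero (a linear final
activation may produce them).

Post-processing, all deterministic and config-exposed:

1. **Foreground mask** — single Otsu threshold computed on `log10(D)` over
   the nonzero support, then binary closing, then a peel of
   `fg_erosion = 1` voxel. The log domain matters: the cubed distance map
   spans orders of magnitude and vanishes at the cell surface, so a linear
   Otsu threshold lands deep inside the cells and recovers only cores
   (measured mask IoU ≈ 0.13 on sphere fixtures), whereas the log histogram
   separates the blur tail from the in-cell distribution about one voxel
   *outside* the true surface (the blur's support inflation, ≈ σ); the
   one-voxel peel compensates. Measured mask IoU on sphere and rod
   fixtures: 0.94–0.97. A plain-Otsu mode (`fg_method="otsu"`) is kept for
   comparison.
2. **Seeds** — connected components (6-connectivity) of the top class of a
   3-class multilevel Otsu on `D − B` within the mask; components smaller
   than `min_seed_voxels = 5` are dropped. Cell cores are bright in `D` and
   dark in `B`, so `D − B` isolates one component per cell even at contacts.
3. **Watershed** — seeded, 6-connected, on the elevation `B − D` restricted
   to the mask: region growth is cheap downhill from each core and expensive
   across the bright inter-cell ridges of `B`.
4. **Cleanup** — objects below `min_object_voxels = 30` (about a tenth of a
   small rod at 0.1 µm voxels) are removed and labels are relabelled
   sequentially.

## Segmentation metrics (`biofilm3d.seg_metrics`)

Matching is greedy in descending IoU above the threshold (default 0.5);
at IoU ≥ 0.5 matches are mutually exclusive, so greedy coincides with the
optimal assignment (guarded by a Hungarian-algorithm oracle test at lower
thresholds with distinct IoUs). CA = TP/(TP+FP+FN) and errors out when no
objects exist anywhere. SSA is the mean matched IoU. SBF1 extracts boundary
voxels as object voxels with a face-adjacent non-object voxel — neighbours
are only looked up inside the array, so a single-slice volume yields the 2D
perimeter — and scores precision/recall with a √3-voxel Euclidean
tolerance via KD-trees, averaged as F1 over matched pairs. Boundary points
are voxels, not mesh points.

The disk-of-diameter-20 versus enclosing-square-of-side-20 example
(rasterized as voxel centres with distance < 10 from the square's centre)
evaluates to IoU 0.79 and SBF1 0.67 under these conventions.

## Shape analysis (`biofilm3d.shapes`)

Per object: voxel count, solidity (voxel count over the rasterized convex
hull volume, the convex-image convention), and ellipsoid-equivalent axis
lengths `4·√λ` from the principal moments of the voxel cloud (plus 1/12 per
axis for the voxel's own extent). The minor-axis ratio is stored both as
long/short (≥ 1, as usually reported) and short/long (≤ 1, used for
thresholding). PCA standardizes features (constant columns dropped with a
warning) and projects onto two components. The rod/odd classifier is a
transparent threshold rule — solidity ≥ 0.85, short/long minor ratio
≥ 0.75, optional volume bounds — replacing a learned shape classifier: no
labelled training objects ship with the package, the thresholds encode the
same separation (merged/fragmented objects lose solidity or cross-section
circularity), and any callable can be substituted.

## Tracking (`biofilm3d.tracking`)

Linking is greedy nearest-neighbour on centroids only: all inter-frame pairs
within `max_link_distance` (1 µm for simulated data, 1.5 µm suggested for
experimental) sorted by distance, ties by ids, both endpoints used once.
Unlinked detections in the later frame are tested for division: the nearest
earlier-frame cell within the distance threshold that is ≥ 1.5× larger in
volume *and* ≥ 1.5× longer becomes the parent. A division rewrites the
parent's surviving track link into a parent-daughter edge, so divisions
always yield two daughter edges (the typed-edge semantics the AOGM metrics
require), and no parent gains more than two daughters. Unlinked detections
failing the test start new tracks.

RM (relative movement) is a *difficulty* measure: per cell with a track
edge, its own displacement divided by the distance to the nearest
non-successor detection in the next frame; it therefore requires known
correspondences and is computed on ground-truth or already-tracked graphs.
Excluding the cell's own successor makes RM = 0 for a static colony.
Frames whose successor frame has fewer than two detections are skipped with
a warning.

The simulator's ground-truth lineage (`lineage_from_colony`) supports
temporal downsampling: a retained cell connects to its most recent retained
ancestor, as a track edge when the id is unchanged and as a parent-daughter
edge otherwise.

## Tracking metrics (`biofilm3d.track_metrics`)

The detection test follows the standard convention the AOGM framework
builds on: an estimated object detects a reference vertex when it covers
more than half of the reference object's voxels; an estimated object
claimed by *m* ≥ 2 reference vertices contributes *m* − 1 missed splits
(NS). Edge operations are counted against the vertex correspondence:
reference edges whose mapped estimated edge exists count as matches
(semantics mismatch → EC), missing ones as EA, estimated edges never used
as a counterpart as ED. `AOGM₀` builds the reference graph from scratch:
one FN-weighted operation per vertex plus one EA-weighted operation per
edge — under the edge-only weights this reduces to the reference edge
count, which is the normalization chosen for `TRA_edge`. An exhaustive
minimal-edit search over estimated-edge subsets verifies the counts on
small random graphs.

## Pipeline, I/O and CLI

`run_pipeline` chains simulate → voxelize → render (photon budget solved
for the requested SBR) → oracle-predict → segment → evaluate (CA over the
IoU grid 0.05–0.95, SSA, SBF1) → track → TRA, with every random draw
derived from one seed; identical seeds reproduce the JSON report exactly.
Volumes are multi-page TIFF (labels 16-bit, widened to 32-bit beyond
65,534 objects with an explicit overflow error when 16-bit is forced;
intensities 32-bit float). Lineages are two CSV tables plus a
cell-tracking-challenge-style track summary file.

## Problem sizes used in the test suite

The dense-colony round trip grows ~286 cells from six seeds (local density
≈ 0.5 by the 10-densest-tiles measure, volume ≈ 170×190×180 voxels) — large
enough for several hundred cell–cell contacts while keeping the whole suite
under a minute. Tracking recovery uses a 31-frame, 4→32-cell colony with
measured RM ≈ 0.06 at full sampling, downsampled 2× and 3× for the
temporal-resolution trend. Metric and EDT oracles run on ≤ 32³ volumes and
≤ 8-vertex graphs where exhaustive enumeration is feasible.

## Known limitations

- The growth model has no substrate, motility, or matrix mechanics;
  colonies are free-floating blobs, and compactness is emergent rather than
  controlled.
- `B` carries no signal for cells farther than `other_distance_range` from
  any neighbour; isolated cells are segmented from `D` alone.
- Greedy linking has no gap closing across skipped frames and no global
  (Hungarian) optimization.
- The oracle predictor bounds what the post-processing can achieve; results
  with a trained network depend on prediction quality and are out of scope
  here.
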