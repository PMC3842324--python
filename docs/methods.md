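# Methods

## Model and assumptions

`halotrack` tracks individual cells in phase-contrast time-lapse movies with
a mean-shift process over an adaptive, sectorized kernel. The underlying
assumptions are:

- after pre-processing, a cell is a compact dark region surrounded by a
  bright halo, both distinguishable from a mid-gray background;
- cells move little enough between frames that the kernel placed at the
  previous position still overlaps the cell (the per-frame mean shift is a
  local search, not a detector);
- cell shape changes smoothly, so per-sector radii adapted on one frame are
  a good starting geometry for the next.

Tracking runs backward in time from user seeds on the last frame. Each
frame's refinement alternates mass-center computation and re-centering until
the center moves less than `conv_tol` (default 0.1 px) or `max_iter`
(default 10) iterations, then adapts the radii once at the converged center.
The adapted radii — not the initial ones — are carried to the preceding
frame.

## Kernel geometry conventions

- Sector *n* of `ndir` spans the angular wedge [(n−1)·2π/ndir, n·2π/ndir),
  sector 1 starting at east; the triangle "radius" is its height along the
  wedge bisector, so the base corners sit on the wedge boundary rays at
  distance r/cos(π/ndir) and the concatenated bases of the initial kernel
  form two regular concentric polygons.
- Pixel centers sit at integer (x = column, y = row) coordinates. Triangle
  membership is **closed**: a pixel on a shared sector boundary contributes
  to both adjacent sectors. An exclusive (half-open) assignment would break
  the dihedral symmetry of the decomposition on the pixel grid — a kernel on
  a circularly symmetric cell would adapt unequal sector radii purely from
  the bookkeeping of boundary pixels. On-edge status is decided with a
  1e-9 cross-product tolerance (well under a nanopixel) so that vertex
  rounding cannot assign boundary pixels asymmetrically; sector boundary
  directions are computed by octant reduction so 90° rotations and diagonal
  mirrors of the grid act exactly.
- Degenerate (zero-area) triangles contain no pixels; with γ = 0 the inner
  mass center is defined as the kernel center (the continuous limit).
- A sector whose region has zero total weight is skipped in the centroid and
  inherits the mean-based radius, which keeps kernels alive near borders.

## Radius adaptation and the expansion factor

The outer radii adapt as r_wn = k·[(1−β)·mean(d) + β·dₙ], clamped to
[r_min, r_max], a convex blend of the mean and per-sector bright-mass-center
distances. With intensity-proportional weights, the bright mass center of a
triangle over a *uniform* region lies at 2/3 of its height, so the blend is
scale-neutral only around k ≈ 3/2: values of k well below 1.5 shrink the
kernel geometrically on any frame dominated by background, while values well
above let it inflate until the clamp. The default k = 1.4 keeps a slight
inward pressure so the kernel stays snug around the halo; β = 0.5 splits the
adaptation between isotropic and per-sector; clamps default to
[4, 35] px for cells of ~9 px body radius.

## Defaults

| parameter | default | meaning |
|---|---|---|
| ndir | 8 | sectors (octagon) |
| r_w_init | 20 px | initial outer radius |
| γ | 0.5 | inner/outer radius ratio |
| P_w, P_b | 1, 1 | bright/dark barycenter weights |
| k | 1.4 | expansion factor (see above) |
| β | 0.5 | anisotropy factor |
| r_min, r_max | 4, 35 px | radius clamps |
| max_iter, conv_tol | 10, 0.1 px | per-frame convergence |
| max_jump | 30 px | lost-track displacement flag |
| tile_size, clip_limit | 64, 0.01 | CLAHE pre-processing |
| pause threshold | 0.1 µm/min | user-set, cell-type dependent |

All defaults were chosen on the synthetic scenarios; for real cell lines
they are starting points to be adjusted once per line and condition.

## Pre-processing

The enhancement operator is contrast-limited adaptive histogram equalization
(CLAHE) on tiles, followed by a global min-max stretch to [0, 255] and
conversion to 8 bits. Any input bit depth is first rescaled to [0, 1];
an `invert` option handles acquisitions whose cells are bright before
equalization. Constant frames carry no contrast and are returned as
mid-gray 128 (avoids a divide-by-zero in the stretch). Equalization is not
idempotent; only range and local ordering are contractual.

## Lost tracks

Three signals end a track early, leaving the earlier frames unfilled while
the tracked span is retained (flagged `lost_at_frame_t`) so lost cells can
still be summarized and compared against completed ones:

- every sector empty (kernel fully off the image);
- zero intensity contrast in the neighborhood under the kernel (nothing for
  the mean shift to grip — e.g. a seed dropped on blank background);
- a per-frame displacement above `max_jump`.

Gradual failures are *not* auto-detected: when two cells pass within a body
diameter the kernel can slide from one to the other smoothly, producing a
"complete" track that follows the wrong cell — on the default synthetic
scenario this affects roughly one cell in ten. This mirrors practice: such
losses are spotted by eye or betrayed by implausible maximum step distances.

## Trajectory statistics

Distances are in µm (um_per_px), times in minutes (min_per_frame). The
persistence d_ttl/d_S-E is reported missing (NaN) for closed paths rather
than infinite, keeping population averages finite. Standard deviations are
sample (n−1) throughout, since per-cell values are estimates from sampled
frames. Pausing uses a strict v < threshold comparison, so a zero threshold
never counts a pause. Step angles are measured against the horizontal with
the image y-axis negated (upward on screen = +90°), in (−180°, 180°]; the
per-cell mean angle is the arithmetic mean of the signed angles by default,
with a circular mean available (`angle_method="circular"`) since signed
averaging of angles near ±180° is ill-behaved. The population report
averages every per-cell descriptor over cells, which realizes the two-level
scheme (mean of per-cell means and mean of per-cell SDs). Group comparison
is a plain unpaired two-sample t-test; two identical zero-variance groups
compare as t = 0, p = 1 by convention.

## The synthetic movie generator

The simulator emulates what the tracker needs from phase-contrast data, not
the optics: dark radially-deformed disks (body level 60) with smooth bright
annular halos (level 200, width 3 px) on a background of 128 with additive
Gaussian noise (SD 8 by default), 8-bit. Motion is a persistent random walk:
per-frame heading perturbation N(0, σ_turn) with σ_turn = 25° by default,
step length N(2, 0.5) px truncated at zero. Paths reflect at the visibility
margin (body + halo fully inside the frame) with the heading component
flipped. Starts are rejection-sampled with a minimum pairwise separation
(50 px default, relaxed automatically in small test frames) inside a 40 px
border margin. Three RNG streams (motion, shape, noise) spawn from one seed,
so changing only the noise level leaves the ground-truth paths untouched.

What the simulator does **not** model — and what passing tests therefore do
not demonstrate — includes: cell division and collision mechanics, texture
and internal structure, focus drift, illumination gradients, halo asymmetry
of true Zernike phase contrast, and cells entering or leaving the field.
Real movies will need per-line parameter adjustment and visual inspection
of tracks.

The bright-body polarity scenario renders the intensity-inverted movie; the
tracker's polarity option correspondingly swaps which nested region is
attracted to bright and to dark pixels.

## Numerical choices and degenerate inputs

- Convergence is declared on a center displacement below `conv_tol`; the
  discrete pixel membership makes the per-frame fixed point an attractor
  *region* of roughly a pixel, so forward and backward passes over the same
  movie agree to the tracking accuracy (~1–1.5 px), not to machine
  precision. Time reversal on a static movie is exact.
- Tracking is fully deterministic: identical inputs give byte-identical
  track tables.
- Out-of-bounds seeds are warned about and skipped; an empty valid-seed list
  is an error. Duplicate seeds are allowed.
- A due-west step reads +180°, not −180° (negative-zero handling).
- Tracks shorter than two points raise an insufficient-data error in every
  statistic.

## Problem sizes used in the test suite

The default validation scenario is 10 cells, 100 frames, 512×512 px,
2 px/frame, noise SD 8; the polarity comparison uses 8 cells, 60 frames,
384×384; the CLI round-trip uses 3 cells, 15 frames, 160×160. These sizes
exercise every code path while keeping the suite quick to run; accuracy on
the default scenario (~1 px mean center error, ~90–100 % of cells well
tracked) is representative of the larger scenarios we ran during
development.

## Known limitations

- No division handling or track splitting; a kernel passing close to
  another cell can swap targets without an automatic flag.
- Shape changes register as small center displacements, inflating speed and
  acceleration sensitivity — inspect Euclidean distances before drawing
  biological conclusions.
- The radius-adaptation expression is one reasonable member of the family
  of blends consistent with the kernel's design (dependencies: expansion
  factor, anisotropy factor, mean and per-sector mass-center distances);
  alternatives (e.g. rank-based dark weighting, cross-frame radius
  smoothing) were not explored.
- The pre-processing operator is fixed to CLAHE; no flat-field correction,
  denoising or drift registration is provided.
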