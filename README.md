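# halotrack

Automated single-cell tracking and migration analysis for phase-contrast
time-lapse microscopy.

Crawling cells imaged by phase contrast appear as dark bodies surrounded by
bright halos on a mid-gray background. Measuring how they migrate — speed,
persistence, pauses, turning — traditionally means clicking on every cell in
every frame, which is slow, tiring and inconsistent between observers.
`halotrack` replaces that with a mean-shift tracker built around an adaptive
polygonal kernel, plus the full set of trajectory descriptors biologists
report, and a synthetic-movie simulator that provides ground truth for
validating the whole pipeline.

## The method

Each cell is approximated by a polygon of `ndir` angular sectors (an octagon
by default). Sector *n* holds two nested isosceles triangles with a common
apex at the cell center (x₀, y₀): the outer region R_wn (height r_wn) is
attracted to bright pixels, the inner region R_bn (height r_bn = γ·r_wn) to
dark pixels. On each frame the tracker repeats:

1. intensity-weighted mass centers g_wn (weight I) and g_bn (weight 255 − I)
   of every region;
2. sector barycenters Cₙ = (P_w·g_wn + P_b·g_bn)/(P_w + P_b);
3. new center = centroid of the Cₙ,

until the center settles, then adapts the outer radii to the cell shape,

    r_wn = k · [(1 − β)·mean(d) + β·dₙ],     dₙ = ‖g_wn − (x₀, y₀)‖,

clamped to [r_min, r_max], where k is an expansion factor and β blends
isotropic (β = 0) against per-sector (β = 1) adaptation. Cells are seeded by
the user on the **last** frame and tracked backward in time; frames are first
contrast-enhanced with tile-based CLAHE so the bodies are dark and the halos
bright. Bright cells on a grey halo are handled by a polarity option that
swaps the roles of the two weights.

From the subpixel tracks the analysis computes, per cell: total distance
d_ttl, Euclidean start-end distance d_S-E, persistence d_ttl/d_S-E, per-step
distance extremes and moments (d_min, d_max, mean, SD), instantaneous speed
and acceleration (mean, SD), percentage of pausing steps (speed below a user
threshold) and the step angle α against the horizontal — and, per
population, the mean over cells of the per-cell means and SDs, with an
unpaired t-test for two-group comparisons.

## Worked example

```python
import dataclasses
import halotrack as hk

# synthetic movie: 5 cells, 60 frames, persistent random walk at 2 px/frame
params = dataclasses.replace(hk.SimParams(), n_cells=5, n_frames=60, seed=7)
stack, paths = hk.render_movie(params)

movie = hk.preprocess_movie(stack, hk.PreprocParams())
seeds = hk.seed_cells(paths[:, -1, :].tolist(), movie[-1])
tracks = hk.track_all(seeds, movie, hk.TrackerParams())

cal = hk.Calibration(um_per_px=0.65, min_per_frame=4.0)
stats = [hk.summarize_cell(t, cal, pause_threshold=0.1) for t in tracks]
print(hk.summarize_population(stats).round(3).to_string(index=False))

_, summary = hk.evaluate_tracks(hk.tracks_to_table(tracks), hk.truth_table(paths))
print({k: round(v, 2) for k, v in summary.items()})
```

prints

```
 n_cells  n_steps  d_ttl   d_SE  persistence  d_min  d_max  step_mean  step_sd  speed_mean  speed_sd  accel_mean  accel_sd  pause_pct  angle_mean
       5     59.0 73.501 24.202        4.358  0.166   2.29      1.246    0.468       0.311     0.117      -0.001     0.046      3.729      11.875
{'n_cells': 5, 'n_complete': 5, 'completion_pct': 100.0, 'mean_err_px': 0.97, 'rmse_px': 1.05}
```

Over 59 four-minute intervals the cells covered 73.5 µm of path for a net
24.2 µm displacement (persistence 4.4 — a moderately tortuous walk), at a
mean instantaneous speed of 0.31 µm/min with 3.7 % of steps counted as
pauses below 0.1 µm/min. The evaluation against the simulator's ground truth
shows all five tracks complete with about 1 px center error.

The same pipeline is available from the shell:

```sh
halotrack simulate --out-dir sim --n-cells 10 --n-frames 100 --seed 1
halotrack preprocess sim/movie.tif pre.tif
halotrack track pre.tif sim/seeds.csv --out tracks.csv --min-per-frame 4
halotrack analyze tracks.csv --um-per-px 0.65 --min-per-frame 4 --out-dir stats
halotrack evaluate tracks.csv sim/truth.csv
```

Track tables are plain CSV (`cell_id, frame, time_min, x_px, y_px,
converged, status`), so trajectories produced by manual tracking tools can
be analyzed by the very same `analyze` step.

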