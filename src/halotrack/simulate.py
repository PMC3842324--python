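"""Synthetic phase-contrast movies with known ground truth.

Cells move by a persistent random walk (heading perturbed by Gaussian turning
noise each frame, step length Gaussian around a mean speed, truncated at
zero) and are rendered as dark, radially deformed disks surrounded by bright
halos on a noisy mid-gray background — the appearance the tracker expects.
Three independent RNG streams (motion, shape, noise) are spawned from one
seed, so changing only the rendering noise level leaves the ground-truth
paths untouched and scenarios stay comparable across noise levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["SimParams", "simulate_paths", "render_frame", "render_movie", "truth_table"]


@dataclass(frozen=True)
class SimParams:
    """Scenario parameters for the synthetic movie generator.

    Geometry is in pixels, intensities in [0, 255], angles in degrees.
    ``speed_px_per_frame`` is the mean step length of the persistent random
    walk and ``persistence_angle_sd`` the standard deviation of the per-frame
    turning angle (0 gives perfectly straight paths).  ``shape_deform_amp``
    is the fractional amplitude of the radial body deformation.  Paths are
    reflected at a margin inside the borders so cells stay fully visible.
    """

    n_cells: int = 10
    n_frames: int = 100
    image_size: tuple[int, int] = (512, 512)  # (H, W)
    body_radius_px: float = 9.0
    body_radius_jitter: float = 1.5
    halo_width_px: float = 3.0
    body_level: float = 60.0
    halo_level: float = 200.0
    background_level: float = 128.0
    speed_px_per_frame: float = 2.0
    speed_sd_px: float = 0.5
    persistence_angle_sd: float = 25.0
    shape_deform_amp: float = 0.1
    noise_sd: float = 8.0
    polarity: str = "dark_body_bright_halo"
    start_margin_px: float = 40.0
    min_separation_px: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_frames < 1:
            raise ValueError("need at least one cell and one frame")
        if self.speed_px_per_frame < 0:
            raise ValueError("speed must be nonnegative")
        if not (
            self.body_level < self.background_level < self.halo_level
        ):
            raise ValueError(
                "dark-body rendering requires body < background < halo levels"
            )


def _streams(params: SimParams) -> tuple[np.random.Generator, ...]:
    motion, shape, noise = np.random.SeedSequence(params.seed).spawn(3)
    return (
        np.random.default_rng(motion),
        np.random.default_rng(shape),
        np.random.default_rng(noise),
    )


def _reflect(v: float, lo: float, hi: float) -> tuple[float, bool]:
    """Reflect a coordinate into [lo, hi]; flag whether it bounced."""
    bounced = False
    while v < lo or v > hi:
        v = 2 * lo - v if v < lo else 2 * hi - v
        bounced = True
    return v, bounced


def simulate_paths(
    params: SimParams, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Ground-truth subpixel centers, shape ``(n_cells, n_frames, 2)`` as (x, y).

    Starts are rejection-sampled inside ``start_margin_px`` with a minimum
    pairwise separation; headings are uniform.  Paths reflect at the visibility
    margin (body plus halo fully inside the frame), and reflection also flips
    the heading component so cells do not creep along the border.
    """
    if rng is None:
        rng, _, _ = _streams(params)
    h, w = params.image_size
    m = params.start_margin_px
    if w - 2 * m <= 0 or h - 2 * m <= 0:
        raise ValueError("image too small for the start margin")

    # rejection-sample starts; relax the separation when the field is too
    # crowded for it (keeps small test scenes feasible and deterministic)
    starts: list[tuple[float, float]] = []
    sep = params.min_separation_px
    misses = 0
    while len(starts) < params.n_cells:
        x = rng.uniform(m, w - 1 - m)
        y = rng.uniform(m, h - 1 - m)
        if all(math.hypot(x - sx, y - sy) >= sep for sx, sy in starts):
            starts.append((x, y))
            misses = 0
        else:
            misses += 1
            if misses >= 1000:
                sep *= 0.8
                misses = 0

    turn_sd = math.radians(params.persistence_angle_sd)
    mr = min(m, params.body_radius_px + params.halo_width_px + 2.0)
    paths = np.empty((params.n_cells, params.n_frames, 2))
    for i, (x, y) in enumerate(starts):
        heading = rng.uniform(0.0, 2.0 * math.pi)
        paths[i, 0] = (x, y)
        for t in range(1, params.n_frames):
            heading += rng.normal(0.0, turn_sd) if turn_sd > 0 else 0.0
            step = max(0.0, rng.normal(params.speed_px_per_frame, params.speed_sd_px))
            x += step * math.cos(heading)
            y += step * math.sin(heading)
            x, bx = _reflect(x, mr, w - 1 - mr)
            y, by = _reflect(y, mr, h - 1 - mr)
            if bx:
                heading = math.pi - heading
            if by:
                heading = -heading
            paths[i, t] = (x, y)
    return paths


def _cell_shape_params(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Per-cell (radius, phase2, phase3) drawn from the shape stream."""
    out = np.empty((params.n_cells, 3))
    out[:, 0] = np.clip(
        rng.normal(params.body_radius_px, params.body_radius_jitter, params.n_cells),
        2.0,
        None,
    )
    out[:, 1:] = rng.uniform(0.0, 2.0 * math.pi, (params.n_cells, 2))
    return out


def render_frame(
    centers: np.ndarray,
    params: SimParams,
    shape_params: Optional[np.ndarray] = None,
    noise_rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one frame: dark deformed disks with bright halos, plus noise.

    ``centers`` is ``(n, 2)`` as (x, y).  Without ``shape_params`` every cell
    is a perfect disk of the mean body radius (useful for symmetry tests);
    without ``noise_rng`` the frame is noise-free.  Bright-body polarity
    inverts the rendered intensities.
    """
    h, w = params.image_size
    canvas = np.full((h, w), params.background_level)
    edge = 1.5  # smooth edge width, px
    for i, (cx, cy) in enumerate(np.atleast_2d(centers)):
        if shape_params is None:
            radius, ph2, ph3 = params.body_radius_px, 0.0, 0.0
            amp = 0.0
        else:
            radius, ph2, ph3 = shape_params[i]
            amp = params.shape_deform_amp
        r_out = radius * (1 + abs(amp)) + params.halo_width_px + 2 * edge
        x0 = max(0, int(math.floor(cx - r_out)))
        x1 = min(w - 1, int(math.ceil(cx + r_out)))
        y0 = max(0, int(math.floor(cy - r_out)))
        y1 = min(h - 1, int(math.ceil(cy + r_out)))
        if x0 > x1 or y0 > y1:
            continue
        xs = np.arange(x0, x1 + 1) - cx
        ys = np.arange(y0, y1 + 1) - cy
        dx, dy = np.meshgrid(xs, ys)
        r = np.hypot(dx, dy)
        if amp != 0.0:
            theta = np.arctan2(dy, dx)
            r_body = radius * (
                1.0
                + amp * (0.7 * np.sin(2 * theta + ph2) + 0.3 * np.sin(3 * theta + ph3))
            )
        else:
            r_body = radius
        w_body = np.clip((r_body - r) / edge + 0.5, 0.0, 1.0)
        w_halo = np.clip((r - r_body) / edge + 0.5, 0.0, 1.0) * np.clip(
            (r_body + params.halo_width_px - r) / edge + 0.5, 0.0, 1.0
        )
        canvas[y0 : y1 + 1, x0 : x1 + 1] += w_body * (
            params.body_level - params.background_level
        ) + w_halo * (params.halo_level - params.background_level)
    if noise_rng is not None and params.noise_sd > 0:
        canvas = canvas + noise_rng.normal(0.0, params.noise_sd, canvas.shape)
    if params.polarity == "bright_body_grey_halo":
        canvas = 255.0 - canvas
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


def render_movie(params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Full scenario: returns ``(stack, paths)``.

    ``stack`` is a ``(n_frames, H, W)`` uint8 movie, ``paths`` the ground
    truth of :func:`simulate_paths`.  Deterministic under ``params.seed``.
    """
    motion, shape, noise = _streams(params)
    paths = simulate_paths(params, rng=motion)
    shape_params = _cell_shape_params(params, shape)
    h, w = params.image_size
    stack = np.empty((params.n_frames, h, w), dtype=np.uint8)
    for t in range(params.n_frames):
        stack[t] = render_frame(paths[:, t, :], params, shape_params, noise)
    return stack, paths


def truth_table(paths: np.ndarray, min_per_frame: float = 1.0) -> pd.DataFrame:
    """Ground truth in the track-table schema (joins against tracker output)."""
    n_cells, n_frames, _ = paths.shape
    rows = {
        "cell_id": np.repeat(np.arange(1, n_cells + 1), n_frames),
        "frame": np.tile(np.arange(n_frames), n_cells),
        "time_min": np.tile(np.arange(n_frames) * min_per_frame, n_cells),
        "x_px": paths[:, :, 0].ravel(),
        "y_px": paths[:, :, 1].ravel(),
        "converged": True,
        "status": "complete",
    }
    return pd.DataFrame(rows)
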