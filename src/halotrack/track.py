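"""Backward mean-shift tracking of seeded cells.

Cells are seeded by the user on the *last* frame of the pre-processed movie
and followed backward in time: on each frame the kernel center is relocated
to the centroid of the sector barycenters until it settles, then the sector
radii adapt to the cell shape and the kernel state is carried to the
preceding frame.  The output is a chronological subpixel track per cell with
a complete/lost status.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .kernel import (
    Kernel,
    KernelConfig,
    init_kernel,
    kernel_centroid,
    region_mass_center,
    sector_center,
    sector_triangles,
    update_radii,
)

log = logging.getLogger(__name__)

__all__ = [
    "TrackerParams",
    "TrackPoint",
    "Track",
    "LostCellError",
    "seed_cells",
    "refine_on_frame",
    "track_cell",
    "track_all",
    "tracks_to_table",
    "table_to_tracks",
    "read_track_table",
    "write_track_table",
]


class LostCellError(RuntimeError):
    """Raised when a kernel can no longer see any cell signal."""


@dataclass(frozen=True)
class TrackerParams:
    """Tracking parameters on top of the kernel configuration.

    max_iter mean-shift iterations per frame (1 reproduces a single step),
    conv_tol center-displacement convergence threshold in pixels, max_jump
    the per-frame displacement above which the track is flagged as lost.
    """

    kernel: KernelConfig = field(default_factory=KernelConfig)
    max_iter: int = 10
    conv_tol: float = 0.1
    max_jump: float = 30.0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.conv_tol <= 0 or self.max_jump <= 0:
            raise ValueError("conv_tol and max_jump must be positive")


@dataclass(frozen=True)
class TrackPoint:
    frame: int
    x: float
    y: float
    converged: bool


@dataclass
class Track:
    """Chronological subpixel centers of one cell.

    ``status`` is ``"complete"`` or ``"lost"``; a lost track stops at
    ``lost_frame`` (frames earlier in time are unfilled) but keeps every
    point over its tracked span so it can still be summarized.
    """

    cell_id: int
    points: list[TrackPoint]
    status: str = "complete"
    lost_frame: Optional[int] = None

    @property
    def complete(self) -> bool:
        return self.status == "complete"

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) in chronological order."""
        return np.array([[p.x, p.y] for p in self.points])


def seed_cells(
    seeds: Union[str, Path, Sequence[Sequence[float]]],
    last_frame: np.ndarray,
) -> list[tuple[int, tuple[float, float]]]:
    """Validate seed positions against the last frame's bounds.

    ``seeds`` is a CSV file with ``x``/``y`` (or ``x_px``/``y_px``) columns or
    a sequence of (x, y) pairs.  Out-of-bounds seeds are dropped with a
    warning; duplicates are allowed (two kernels may start on one cell).
    Returns ``(cell_id, (x, y))`` pairs numbered 1..N in input order.
    """
    if isinstance(seeds, (str, Path)):
        df = pd.read_csv(seeds)
        cols = {c.lower(): c for c in df.columns}
        xcol = cols.get("x", cols.get("x_px"))
        ycol = cols.get("y", cols.get("y_px"))
        if xcol is None or ycol is None:
            raise ValueError(f"seed file {seeds} needs x/y (or x_px/y_px) columns")
        pairs = list(zip(df[xcol].astype(float), df[ycol].astype(float)))
    else:
        pairs = [(float(s[0]), float(s[1])) for s in seeds]
    if not pairs:
        raise ValueError("empty seed list")
    h, w = last_frame.shape[:2]
    kept: list[tuple[int, tuple[float, float]]] = []
    for x, y in pairs:
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            warnings.warn(f"seed ({x}, {y}) outside image bounds; skipped")
            continue
        kept.append((len(kept) + 1, (x, y)))
    if not kept:
        raise ValueError("no valid seeds inside image bounds")
    return kept


def _region_modes(cfg: KernelConfig) -> tuple[str, str]:
    """(outer, inner) weighting modes; bright-body polarity swaps the roles."""
    if cfg.polarity == "bright_body_grey_halo":
        return "dark", "bright"
    return "bright", "dark"


def _sector_pass(
    kernel: Kernel, frame: np.ndarray, cfg: KernelConfig
) -> tuple[list, list]:
    """Mass centers (g_w, g_b) of every sector at the current kernel state."""
    outer_mode, inner_mode = _region_modes(cfg)
    g_w, g_b = [], []
    for n in range(1, cfg.ndir + 1):
        geo = sector_triangles(kernel, n)
        g_w.append(region_mass_center(frame, geo.outer_triangle, outer_mode))
        if kernel.r_b[n - 1] == 0.0:
            g_b.append(kernel.center)  # gamma=0: inner region degenerates to the center
        else:
            g_b.append(region_mass_center(frame, geo.inner_triangle, inner_mode))
    return g_w, g_b


def refine_on_frame(
    kernel: Kernel, frame: np.ndarray, params: TrackerParams
) -> tuple[Kernel, bool]:
    """Converge the kernel center on one frame, then adapt the radii once.

    Repeats {mass centers -> sector barycenters -> new center} until the
    center moves less than ``conv_tol`` or ``max_iter`` is reached, then
    recomputes the bright mass centers at the converged center and applies
    :func:`update_radii`.  Returns ``(kernel, converged)``.

    Raises :class:`LostCellError` when no sector yields a barycenter.
    """
    cfg = params.kernel
    converged = False
    for _ in range(params.max_iter):
        g_w, g_b = _sector_pass(kernel, frame, cfg)
        centers = [
            sector_center(gw, gb, cfg.p_w, cfg.p_b) for gw, gb in zip(g_w, g_b)
        ]
        new_center = kernel_centroid(centers)
        if new_center is None:
            raise LostCellError("all sectors empty")
        shift = math.hypot(
            new_center[0] - kernel.center[0], new_center[1] - kernel.center[1]
        )
        kernel = Kernel(center=new_center, r_w=kernel.r_w, r_b=kernel.r_b)
        if shift < params.conv_tol:
            converged = True
            break
    g_w, _ = _sector_pass(kernel, frame, cfg)
    return update_radii(kernel, g_w, cfg), converged


def _no_signal(kernel, frame: np.ndarray) -> bool:
    """True when the neighborhood under the kernel carries zero contrast.

    A constant patch gives the mean-shift nothing to grip: every mass center
    collapses onto the region centroid and the kernel would sit still forever,
    so the cell is reported lost instead.  Noisy background is NOT flagged —
    such losses surface as implausible jumps or are spotted by eye.
    """
    h, w = frame.shape
    cx, cy = kernel.center
    r = float(np.max(kernel.r_w))
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 1)
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 1)
    if x0 >= x1 or y0 >= y1:
        return True
    patch = frame[y0:y1, x0:x1]
    return bool(patch.max() == patch.min())


def track_cell(
    seed: Sequence[float],
    movie: np.ndarray,
    params: TrackerParams,
    cell_id: int = 1,
) -> Track:
    """Track one cell backward from a seed on the last frame.

    The kernel is initialized at the seed on frame T-1, refined there, and
    carried frame by frame to t = 0.  A per-frame displacement above
    ``max_jump`` or a lost-cell signal stops the track with a lost status;
    earlier frames remain unfilled.  Points come back in chronological order.
    """
    movie = np.asarray(movie)
    n_frames, h, w = movie.shape
    if n_frames < 2:
        raise ValueError("movie needs at least 2 frames")
    x, y = float(seed[0]), float(seed[1])
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise ValueError(f"seed ({x}, {y}) outside image bounds")

    kernel = init_kernel((x, y), params.kernel)
    collected: list[TrackPoint] = []  # backward order
    status, lost_frame = "complete", None
    prev: Optional[tuple[float, float]] = None
    for t in range(n_frames - 1, -1, -1):
        try:
            if _no_signal(kernel, movie[t]):
                raise LostCellError("no intensity structure under the kernel")
            kernel, conv = refine_on_frame(kernel, movie[t], params)
        except LostCellError:
            status, lost_frame = "lost", t
            break
        cx, cy = kernel.center
        if prev is not None and math.hypot(cx - prev[0], cy - prev[1]) > params.max_jump:
            status, lost_frame = "lost", t
            break
        collected.append(TrackPoint(frame=t, x=cx, y=cy, converged=conv))
        prev = (cx, cy)
    return Track(
        cell_id=cell_id,
        points=list(reversed(collected)),
        status=status,
        lost_frame=lost_frame,
    )


def track_all(
    seeds: Sequence[tuple[int, tuple[float, float]]],
    movie: np.ndarray,
    params: TrackerParams,
) -> list[Track]:
    """Track every seeded cell independently; result order follows seed order.

    Per-cell failures do not abort the batch; lost cells are logged (typically
    cells interacting too closely or entering division).
    """
    tracks = []
    for cell_id, pos in seeds:
        track = track_cell(pos, movie, params, cell_id=cell_id)
        if not track.complete:
            log.warning("cell %d lost at frame %s", cell_id, track.lost_frame)
        tracks.append(track)
    log.info(
        "tracked %d cells, %d complete", len(tracks), sum(t.complete for t in tracks)
    )
    return tracks


# --- track-table interchange (CSV) -------------------------------------------

_COLUMNS = ["cell_id", "frame", "time_min", "x_px", "y_px", "converged", "status"]


def tracks_to_table(tracks: Sequence[Track], min_per_frame: float = 1.0) -> pd.DataFrame:
    """One row per tracked point, chronological within each cell."""
    rows = []
    for tr in tracks:
        status = (
            "complete" if tr.complete else f"lost_at_frame_{tr.lost_frame}"
        )
        for p in tr.points:
            rows.append(
                (tr.cell_id, p.frame, p.frame * min_per_frame, p.x, p.y, p.converged, status)
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def table_to_tracks(df: pd.DataFrame) -> list[Track]:
    """Rebuild :class:`Track` objects from a track table."""
    tracks = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        status_str = str(grp["status"].iloc[0])
        lost_frame = None
        status = "complete"
        if status_str.startswith("lost"):
            status = "lost"
            tail = status_str.rsplit("_", 1)[-1]
            lost_frame = int(tail) if tail.isdigit() else None
        points = [
            TrackPoint(frame=int(r.frame), x=float(r.x_px), y=float(r.y_px),
                       converged=bool(r.converged))
            for r in grp.itertuples()
        ]
        tracks.append(
            Track(cell_id=int(cell_id), points=points, status=status, lost_frame=lost_frame)
        )
    return tracks


def write_track_table(path: Union[str, Path], df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_track_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table {path} missing columns: {sorted(missing)}")
    return df
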