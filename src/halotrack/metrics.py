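"""Cell-migration descriptors computed from tracks.

Per cell: total path length, start-end (Euclidean) distance, persistence
(their ratio), per-step distance extremes and moments, instantaneous speeds
and accelerations, pause percentage below a user speed threshold, and the
per-step displacement angle against the horizontal.  Per population: the
two-level scheme — mean over cells of the per-cell means AND of the per-cell
standard deviations — plus a plain unpaired t-test for two-group comparisons.

Angles use the mathematical orientation (image y axis flipped), measured
against the horizontal, counter-clockwise positive, in (-180, 180] degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .track import Track

__all__ = [
    "Calibration",
    "TrajectoryStats",
    "InsufficientDataError",
    "step_distances",
    "total_and_euclidean",
    "step_extremes_and_moments",
    "speeds_and_accelerations",
    "pause_fraction",
    "step_angles",
    "summarize_cell",
    "summarize_population",
    "compare_groups",
    "stats_to_table",
]


class InsufficientDataError(ValueError):
    """A track (or group) is too short for the requested statistic."""


@dataclass(frozen=True)
class Calibration:
    """Spatial and temporal scale: micrometers per pixel, minutes per frame."""

    um_per_px: float = 1.0
    min_per_frame: float = 4.0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0 or self.min_per_frame <= 0:
            raise ValueError("calibration factors must be positive")


@dataclass
class TrajectoryStats:
    """Migration descriptors of one cell.

    Distances in um, speeds in um/min, accelerations in um/min^2, angles in
    degrees, pause in percent.  ``persistence`` is total/Euclidean distance,
    NaN (missing) for closed paths; it is >= 1 whenever defined.
    """

    cell_id: int
    n_steps: int
    d_ttl: float
    d_SE: float
    persistence: float
    d_min: float
    d_max: float
    step_mean: float
    step_sd: float
    speed_mean: float
    speed_sd: float
    accel_mean: float
    accel_sd: float
    pause_pct: float
    angle_mean: float
    status: str = "complete"


def _positions(track: Track | np.ndarray) -> np.ndarray:
    pos = track.positions() if isinstance(track, Track) else np.asarray(track, float)
    if pos.ndim != 2 or pos.shape[1] != 2 or len(pos) < 2:
        raise InsufficientDataError("need at least 2 track points")
    return pos


def step_distances(track: Track | np.ndarray, cal: Calibration) -> np.ndarray:
    """Distances covered between adjacent frames, um; length n_points - 1."""
    pos = _positions(track)
    return cal.um_per_px * np.hypot(*np.diff(pos, axis=0).T)


def total_and_euclidean(
    track: Track | np.ndarray, cal: Calibration
) -> tuple[float, float, float]:
    """(d_ttl, d_SE, persistence); persistence is NaN when d_SE = 0."""
    pos = _positions(track)
    steps = step_distances(pos, cal)
    d_ttl = float(steps.sum())
    d_se = float(cal.um_per_px * math.hypot(*(pos[-1] - pos[0])))
    persistence = d_ttl / d_se if d_se > 0 else float("nan")
    return d_ttl, d_se, persistence


def step_extremes_and_moments(
    steps: Sequence[float],
) -> tuple[float, float, float, float]:
    """(d_min, d_max, mean, sample sd) of the per-step distances."""
    s = np.asarray(steps, float)
    if s.size == 0:
        raise InsufficientDataError("no steps")
    sd = float(s.std(ddof=1)) if s.size > 1 else 0.0
    return float(s.min()), float(s.max()), float(s.mean()), sd


def speeds_and_accelerations(
    steps: Sequence[float], cal: Calibration
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous speeds v_t = s_t/dt (um/min) and their finite-difference
    accelerations a_t = (v_{t+1} - v_t)/dt (um/min^2); one fewer acceleration
    than speeds."""
    v = np.asarray(steps, float) / cal.min_per_frame
    a = np.diff(v) / cal.min_per_frame
    return v, a


def pause_fraction(speeds: Sequence[float], threshold: float) -> float:
    """Percentage of steps whose speed is strictly below the threshold."""
    if threshold < 0:
        raise ValueError("pause threshold must be >= 0")
    v = np.asarray(speeds, float)
    if v.size == 0:
        raise InsufficientDataError("no speeds")
    return 100.0 * float((v < threshold).sum()) / v.size


def step_angles(track: Track | np.ndarray) -> np.ndarray:
    """Displacement angle per step, degrees in (-180, 180].

    Measured against the horizontal with the image y axis negated so that
    upward motion on screen is +90 deg.  Zero-length steps give NaN.
    """
    pos = _positions(track)
    d = np.diff(pos, axis=0)
    with np.errstate(invalid="ignore"):
        # +0.0 clears negative zeros so a due-west step reads +180, not -180
        ang = np.degrees(np.arctan2(-d[:, 1] + 0.0, d[:, 0]))
    ang[(d[:, 0] == 0) & (d[:, 1] == 0)] = np.nan
    return ang


def _angle_mean(angles: np.ndarray, method: str) -> float:
    valid = angles[~np.isnan(angles)]
    if valid.size == 0:
        return float("nan")
    if method == "signed":
        return float(valid.mean())
    if method == "circular":
        rad = np.radians(valid)
        return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))
    raise ValueError(f"unknown angle method {method!r}")


def summarize_cell(
    track: Track,
    cal: Calibration,
    pause_threshold: float = 0.1,
    angle_method: str = "signed",
) -> TrajectoryStats:
    """Assemble every descriptor for one cell over its tracked span.

    Lost tracks are summarized over the frames they cover and keep their
    status flag so tracked-vs-lost populations can be compared.
    """
    steps = step_distances(track, cal)
    d_ttl, d_se, persistence = total_and_euclidean(track, cal)
    d_min, d_max, s_mean, s_sd = step_extremes_and_moments(steps)
    v, a = speeds_and_accelerations(steps, cal)
    a_sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return TrajectoryStats(
        cell_id=track.cell_id,
        n_steps=len(steps),
        d_ttl=d_ttl,
        d_SE=d_se,
        persistence=persistence,
        d_min=d_min,
        d_max=d_max,
        step_mean=s_mean,
        step_sd=s_sd,
        speed_mean=float(v.mean()),
        speed_sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        accel_mean=float(a.mean()) if a.size else 0.0,
        accel_sd=a_sd,
        pause_pct=pause_fraction(v, pause_threshold),
        angle_mean=_angle_mean(step_angles(track), angle_method),
        status=track.status,
    )


_NUMERIC = [
    f.name
    for f in dc_fields(TrajectoryStats)
    if f.name not in ("cell_id", "status")
]


def stats_to_table(stats: Sequence[TrajectoryStats]) -> pd.DataFrame:
    """Per-cell stats as a DataFrame, one row per cell."""
    return pd.DataFrame(
        [{**{"cell_id": s.cell_id, "status": s.status},
          **{k: getattr(s, k) for k in _NUMERIC}} for s in stats]
    )


def summarize_population(stats: Sequence[TrajectoryStats]) -> pd.DataFrame:
    """Population report: mean over cells of every per-cell descriptor.

    Because the per-cell table already carries both the per-cell means and
    the per-cell standard deviations, averaging every column realizes the
    two-level scheme (mean of means and mean of SDs).  NaN persistences
    (closed paths) are excluded from their average.  Returns a one-row frame
    with an ``n_cells`` column.
    """
    if not stats:
        raise InsufficientDataError("empty population")
    df = stats_to_table(stats)
    out = df[_NUMERIC].mean(skipna=True).to_frame().T
    out.insert(0, "n_cells", len(stats))
    return out


def compare_groups(
    stats_a: Sequence[TrajectoryStats],
    stats_b: Sequence[TrajectoryStats],
    column: str,
) -> tuple[float, float]:
    """Standard unpaired two-sample t-test on one per-cell descriptor.

    Returns ``(t, p)``.  Two identical zero-variance groups compare equal
    (t = 0, p = 1) rather than propagating a 0/0.
    """
    a = stats_to_table(stats_a)[column].dropna().to_numpy(float)
    b = stats_to_table(stats_b)[column].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 cells")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(math.copysign(math.inf, a.mean() - b.mean())), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
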