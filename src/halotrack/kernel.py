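"""Sectorized nested-triangle mean-shift kernel.

A cell on a phase-contrast frame is approximated by a polygon split into
``ndir`` angular sectors.  Each sector holds two nested isosceles triangles
sharing their apex at the kernel center: the outer triangle (height ``r_wn``)
is attracted towards bright pixels (the halo), the inner one (height
``r_bn = gamma * r_wn``) towards dark pixels (the cell body).  Intensity-
weighted mass centers of the two regions are blended into a per-sector
barycenter; the centroid of the sector barycenters relocates the kernel.
After re-centering, the outer radii adapt to the cell shape through an
expansion factor ``k`` and an anisotropy factor ``beta``.

All positions are subpixel ``(x, y)`` with ``x`` the column and ``y`` the row;
pixel centers sit at integer coordinates, origin at the top-left pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

Polarity = Literal["dark_body_bright_halo", "bright_body_grey_halo"]

__all__ = [
    "KernelConfig",
    "Kernel",
    "SectorGeometry",
    "init_kernel",
    "sector_triangles",
    "pixels_in_region",
    "region_mass_center",
    "sector_center",
    "kernel_centroid",
    "update_radii",
]


@dataclass(frozen=True)
class KernelConfig:
    """User parameters of the adaptive kernel.

    Parameters
    ----------
    ndir : int
        Number of angular sectors (>= 3).  8 gives the usual octagon.
    r_w_init : float
        Initial outer radius (triangle height), pixels.
    gamma : float
        Ratio of inner to outer radius, ``r_bn = gamma * r_wn``, in [0, 1].
    p_w, p_b : float
        Barycentric weights of the bright and dark mass centers; their sum
        must be positive.
    k_expand : float
        Multiplicative gain on the adapted radii; keeps the kernel slightly
        larger than the measured cell extent.
    beta : float
        Anisotropy factor in [0, 1]: 0 adapts all sectors to the mean
        mass-center distance (isotropic), 1 adapts each sector independently.
    r_min, r_max : float
        Clamps applied to the outer radii after every adaptation, pixels.
    polarity : str
        ``"dark_body_bright_halo"`` (phase-contrast default) or
        ``"bright_body_grey_halo"``; the latter swaps which region is
        attracted to dark vs. bright pixels.
    """

    ndir: int = 8
    r_w_init: float = 20.0
    gamma: float = 0.5
    p_w: float = 1.0
    p_b: float = 1.0
    k_expand: float = 1.4
    beta: float = 0.5
    r_min: float = 4.0
    r_max: float = 35.0
    polarity: Polarity = "dark_body_bright_halo"

    def __post_init__(self) -> None:
        if self.ndir < 3:
            raise ValueError(f"ndir must be >= 3, got {self.ndir}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.p_w < 0 or self.p_b < 0 or self.p_w + self.p_b <= 0:
            raise ValueError("weights must be nonnegative with P_w + P_b > 0")
        if self.k_expand <= 0:
            raise ValueError("k_expand must be positive")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not 0 < self.r_min <= self.r_w_init <= self.r_max:
            raise ValueError(
                "radius clamps must satisfy 0 < r_min <= r_w_init <= r_max"
            )
        if self.polarity not in ("dark_body_bright_halo", "bright_body_grey_halo"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class Kernel:
    """Adaptive kernel state of one cell on one frame.

    ``center`` is the subpixel cell center; ``r_w`` and ``r_b`` hold the
    per-sector outer and inner radii (``len == ndir``) with
    ``r_b = gamma * r_w`` maintained by every update.
    """

    center: tuple[float, float]
    r_w: np.ndarray
    r_b: np.ndarray

    @property
    def ndir(self) -> int:
        return len(self.r_w)


@dataclass(frozen=True)
class SectorGeometry:
    """Outer and inner triangle of one sector, apex at the kernel center."""

    index: int
    outer_triangle: np.ndarray  # (3, 2) float, rows (apex, base start, base end)
    inner_triangle: np.ndarray


def init_kernel(seed: Sequence[float], cfg: KernelConfig) -> Kernel:
    """Create the generic kernel at a user seed position.

    All outer radii start equal to ``cfg.r_w_init`` and all inner radii to
    ``gamma * r_w_init``, so the concatenated triangle bases form two regular
    concentric ``ndir``-gons.
    """
    x, y = float(seed[0]), float(seed[1])
    r_w = np.full(cfg.ndir, float(cfg.r_w_init))
    return Kernel(center=(x, y), r_w=r_w, r_b=cfg.gamma * r_w)


def _unit_dir(j: int, ndir: int) -> tuple[float, float]:
    """Unit vector at angle 2*pi*j/ndir, exactly symmetric on the pixel grid.

    Plain cos/sin of the full angle breaks the dihedral symmetry of the
    sector decomposition in floating point (e.g. ``cos(pi/4) != sin(pi/4)``
    by one ulp, ``cos(pi/2) != 0``), which would assign pixels on shared
    boundary rays asymmetrically.  Reducing the angle to the first octant and
    mapping back by swaps and negations makes rotations by 90 deg and the
    diagonal mirror act exactly, so symmetric images yield symmetric sectors.
    """
    num = (8 * j) % (8 * ndir)
    octant, rem = divmod(num, ndir)
    if rem == 0 and octant % 2 == 1:  # exact diagonal
        c = s = math.sqrt(0.5)
    elif octant % 2 == 0:
        a = (math.pi / 4.0) * (rem / ndir)
        c, s = math.cos(a), math.sin(a)
    else:
        b = (math.pi / 4.0) * ((ndir - rem) / ndir)
        c, s = math.sin(b), math.cos(b)
    return {
        0: (c, s), 1: (c, s), 2: (-s, c), 3: (-s, c),
        4: (-c, -s), 5: (-c, -s), 6: (s, -c), 7: (s, -c),
    }[octant]


def _sector_triangle(
    center: tuple[float, float], radius: float, n: int, ndir: int
) -> np.ndarray:
    """Vertices (apex, base start, base end) of sector ``n`` (1-based).

    Sector ``n`` spans the angular wedge [(n-1)*2pi/ndir, n*2pi/ndir), so the
    wedge bisector sits at (n - 1/2)*2pi/ndir.  The triangle height along the
    bisector equals ``radius``: the two base corners lie on the wedge boundary
    rays at distance radius / cos(pi/ndir).
    """
    leg = radius / math.cos(math.pi / ndir)
    cx, cy = center
    u0 = _unit_dir(n - 1, ndir)
    u1 = _unit_dir(n, ndir)
    return np.array(
        [
            [cx, cy],
            [cx + leg * u0[0], cy + leg * u0[1]],
            [cx + leg * u1[0], cy + leg * u1[1]],
        ]
    )


def sector_triangles(kernel: Kernel, n: int) -> SectorGeometry:
    """Return the nested outer/inner triangles of sector ``n`` (1-based)."""
    ndir = kernel.ndir
    if not 1 <= n <= ndir:
        raise IndexError(f"sector index {n} out of range 1..{ndir}")
    return SectorGeometry(
        index=n,
        outer_triangle=_sector_triangle(kernel.center, kernel.r_w[n - 1], n, ndir),
        inner_triangle=_sector_triangle(kernel.center, kernel.r_b[n - 1], n, ndir),
    )


def _cross(ax, ay, bx, by, px, py):
    return (bx - ax) * (py - ay) - (by - ay) * (px - ax)


# on-edge slack for pixel membership; absorbs vertex rounding without ever
# reaching a pixel that is meaningfully (> ~1e-10 px) outside the triangle
_EDGE_TOL = 1e-9


def pixels_in_region(
    tri: np.ndarray, image_shape: tuple[int, int]
) -> np.ndarray:
    """Integer pixel coordinates whose centers lie inside a triangle.

    Membership is closed (points on an edge belong to the triangle), so
    pixels on the shared boundary ray of two adjacent sectors contribute to
    both — symmetrically, which preserves the dihedral symmetry of the sector
    decomposition on the pixel grid.  "On an edge" is decided with a small
    cross-product tolerance (1e-9, i.e. well under a nanopixel) so that the
    rounding of triangle vertices cannot assign boundary pixels asymmetrically.
    A degenerate (zero-area) triangle yields the empty set.  Output is clipped
    to image bounds and returned as an ``(N, 2)`` int array of ``(x, y)``
    pairs, deterministic row order.
    """
    tri = np.asarray(tri, dtype=float)
    h, w = int(image_shape[0]), int(image_shape[1])
    (ax, ay), (bx, by), (cx, cy) = tri
    area2 = _cross(ax, ay, bx, by, cx, cy)
    if area2 == 0.0:
        return np.empty((0, 2), dtype=np.intp)
    if area2 < 0.0:  # orient counter-clockwise in (x, y)
        (bx, by), (cx, cy) = (cx, cy), (bx, by)

    x0 = max(0, int(math.ceil(min(ax, bx, cx))))
    x1 = min(w - 1, int(math.floor(max(ax, bx, cx))))
    y0 = max(0, int(math.ceil(min(ay, by, cy))))
    y1 = min(h - 1, int(math.floor(max(ay, by, cy))))
    if x0 > x1 or y0 > y1:
        return np.empty((0, 2), dtype=np.intp)

    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    px, py = np.meshgrid(xs, ys)
    inside = (
        (_cross(ax, ay, bx, by, px, py) >= -_EDGE_TOL)
        & (_cross(bx, by, cx, cy, px, py) >= -_EDGE_TOL)
        & (_cross(cx, cy, ax, ay, px, py) >= -_EDGE_TOL)
    )
    return np.column_stack([px[inside], py[inside]]).astype(np.intp)


def region_mass_center(
    image: np.ndarray, tri: np.ndarray, mode: Literal["bright", "dark"]
) -> Optional[tuple[float, float]]:
    """Intensity-weighted centroid of the pixels inside a triangle.

    The frame must already be pre-processed to the [0, 255] range.  Weights
    are ``I(p)`` in bright mode and ``255 - I(p)`` in dark mode.  Returns
    ``None`` when the region holds no pixel or the total weight is zero.
    """
    pix = pixels_in_region(tri, image.shape)
    if len(pix) == 0:
        return None
    vals = image[pix[:, 1], pix[:, 0]].astype(float)
    w = vals if mode == "bright" else 255.0 - vals
    total = w.sum()
    if total <= 0.0:
        return None
    return (float((w * pix[:, 0]).sum() / total), float((w * pix[:, 1]).sum() / total))


def sector_center(
    g_w: Optional[Sequence[float]],
    g_b: Optional[Sequence[float]],
    p_w: float,
    p_b: float,
) -> Optional[tuple[float, float]]:
    """Barycenter C_n of the bright and dark mass centers with weights P_w, P_b.

    If one mass center is missing the other is returned; if both are missing
    the sector contributes nothing (``None``).
    """
    if g_w is None and g_b is None:
        return None
    if g_b is None:
        return (float(g_w[0]), float(g_w[1]))
    if g_w is None:
        return (float(g_b[0]), float(g_b[1]))
    s = p_w + p_b
    return (
        (p_w * g_w[0] + p_b * g_b[0]) / s,
        (p_w * g_w[1] + p_b * g_b[1]) / s,
    )


def kernel_centroid(
    sector_centers: Sequence[Optional[Sequence[float]]],
) -> Optional[tuple[float, float]]:
    """Unweighted mean of the valid sector barycenters; ``None`` if none."""
    pts = [c for c in sector_centers if c is not None]
    if not pts:
        return None
    arr = np.asarray(pts, dtype=float)
    m = arr.mean(axis=0)
    return (float(m[0]), float(m[1]))


def update_radii(
    kernel: Kernel,
    g_w: Sequence[Optional[Sequence[float]]],
    cfg: KernelConfig,
) -> Kernel:
    """Adapt the outer radii to the cell shape at the current center.

    For each sector the distance ``d_n`` from the bright mass center to the
    kernel center is measured; the new outer radius blends the mean distance
    with the per-sector one,

        r_wn = k * [(1 - beta) * mean(d) + beta * d_n],

    clamped to ``[r_min, r_max]``.  Sectors with a missing mass center fall
    back to the mean-based radius.  Inner radii follow ``r_bn = gamma * r_wn``.
    If every mass center is missing the radii are left unchanged.
    """
    cx, cy = kernel.center
    d = np.full(kernel.ndir, np.nan)
    for i, g in enumerate(g_w):
        if g is not None:
            d[i] = math.hypot(g[0] - cx, g[1] - cy)
    valid = ~np.isnan(d)
    if not valid.any():
        return Kernel(center=kernel.center, r_w=kernel.r_w.copy(), r_b=kernel.r_b.copy())
    mean_d = d[valid].mean()
    d = np.where(valid, d, mean_d)
    r_w = cfg.k_expand * ((1.0 - cfg.beta) * mean_d + cfg.beta * d)
    r_w = np.clip(r_w, cfg.r_min, cfg.r_max)
    return Kernel(center=kernel.center, r_w=r_w, r_b=cfg.gamma * r_w)
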