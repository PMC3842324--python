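"""Independent brute-force oracles used to cross-check the geometry code.

Everything here is written against the *stated conventions* (closed triangle
membership, intensity weights, barycentric blends) with plain per-element
Python, deliberately avoiding the vectorized code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def cross(a, b, p) -> float:
    return (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])


EDGE_TOL = 1e-9  # closed-membership on-edge slack, same convention as the package


def point_in_triangle(p, tri) -> bool:
    """Closed membership (edge tolerance 1e-9); degenerate triangles empty."""
    a, b, c = [tuple(map(float, v)) for v in tri]
    area2 = cross(a, b, c)
    if area2 == 0.0:
        return False
    if area2 < 0.0:
        b, c = c, b
    return (
        cross(a, b, p) >= -EDGE_TOL
        and cross(b, c, p) >= -EDGE_TOL
        and cross(c, a, p) >= -EDGE_TOL
    )


def pixels_in_region_bruteforce(tri, image_shape):
    """Scan every pixel of the image; O(H*W) point-in-triangle test."""
    h, w = image_shape
    return sorted(
        (x, y)
        for y in range(h)
        for x in range(w)
        if point_in_triangle((float(x), float(y)), tri)
    )


def mass_center_bruteforce(image, tri, mode):
    """Per-pixel weighted-mean recomputation of the region mass center."""
    sx = sy = sw = 0.0
    for x, y in pixels_in_region_bruteforce(tri, image.shape):
        v = float(image[y, x])
        wgt = v if mode == "bright" else 255.0 - v
        sx += wgt * x
        sy += wgt * y
        sw += wgt
    if sw <= 0.0:
        return None
    return (sx / sw, sy / sw)


def barycenter(g_w, g_b, p_w, p_b):
    s = p_w + p_b
    return ((p_w * g_w[0] + p_b * g_b[0]) / s, (p_w * g_w[1] + p_b * g_b[1]) / s)


def radii_update_bruteforce(center, g_w_list, k, beta, r_min, r_max, gamma):
    """Direct evaluation of the adaptive-radius blend, one sector at a time."""
    d = [
        math.hypot(g[0] - center[0], g[1] - center[1])
        for g in g_w_list
        if g is not None
    ]
    mean_d = sum(d) / len(d)
    out_w, out_b = [], []
    for g in g_w_list:
        dn = (
            math.hypot(g[0] - center[0], g[1] - center[1])
            if g is not None
            else mean_d
        )
        r = k * ((1.0 - beta) * mean_d + beta * dn)
        r = min(max(r, r_min), r_max)
        out_w.append(r)
        out_b.append(gamma * r)
    return np.array(out_w), np.array(out_b)


def random_triangle(rng, lo=-5.0, hi=25.0):
    return rng.uniform(lo, hi, size=(3, 2))
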