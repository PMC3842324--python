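"""Burn tracks into a movie for visual inspection."""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import disk, line

# distinct RGB colors cycled over cells
_PALETTE = np.array(
    [
        (255, 64, 64), (64, 200, 64), (80, 120, 255), (255, 200, 0),
        (0, 220, 220), (255, 0, 255), (255, 140, 0), (150, 255, 150),
        (200, 160, 255), (255, 255, 255),
    ],
    dtype=np.uint8,
)


def overlay_tracks(stack: np.ndarray, tracks: pd.DataFrame) -> np.ndarray:
    """Return an RGB copy of the movie with a dot per cell center and the
    path up to each frame drawn as a polyline."""
    t, h, w = stack.shape
    rgb = np.repeat(stack[..., None], 3, axis=-1).astype(np.uint8)
    for cell_id, grp in tracks.groupby("cell_id"):
        color = _PALETTE[(int(cell_id) - 1) % len(_PALETTE)]
        grp = grp.sort_values("frame")
        xs = grp["x_px"].to_numpy(float)
        ys = grp["y_px"].to_numpy(float)
        frames = grp["frame"].to_numpy(int)
        for i, f in enumerate(frames):
            if not 0 <= f < t:
                continue
            for j in range(1, i + 1):
                rr, cc = line(
                    int(round(ys[j - 1])), int(round(xs[j - 1])),
                    int(round(ys[j])), int(round(xs[j])),
                )
                ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                rgb[f, rr[ok], cc[ok]] = color
            rr, cc = disk((ys[i], xs[i]), 2.5, shape=(h, w))
            rgb[f, rr, cc] = color
    return rgb
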