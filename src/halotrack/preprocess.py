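"""Phase-contrast frame pre-processing.

Raw frames are locally contrast-enhanced and histogram-equalized so that cell
bodies come out dark and their surrounding halos bright — the appearance the
mean-shift kernel is built for.  The enhancement operator is contrast-limited
adaptive histogram equalization (CLAHE) on tiles, followed by a global
min-max rescale to the 8-bit range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage import exposure

log = logging.getLogger(__name__)

__all__ = ["PreprocParams", "preprocess_frame", "preprocess_movie"]


@dataclass(frozen=True)
class PreprocParams:
    """Pre-processing parameters.

    tile_size : local equalization window in pixels (>= 8).
    clip_limit : CLAHE contrast-limiting fraction in (0, 1].
    invert : pre-invert frames whose cells are bright on dark background.
    """

    tile_size: int = 64
    clip_limit: float = 0.01
    invert: bool = False

    def __post_init__(self) -> None:
        if self.tile_size < 8:
            raise ValueError(f"tile_size must be >= 8, got {self.tile_size}")
        if not 0.0 < self.clip_limit <= 1.0:
            raise ValueError(f"clip_limit must be in (0, 1], got {self.clip_limit}")


def _to_unit_float(frame: np.ndarray) -> np.ndarray:
    """Rescale any single-channel bit depth to float in [0, 1]."""
    if frame.ndim != 2:
        raise ValueError(
            f"expected a single-channel 2-D frame, got shape {frame.shape}"
        )
    f = frame.astype(float)
    if np.issubdtype(frame.dtype, np.integer):
        f /= float(np.iinfo(frame.dtype).max)
    else:
        lo, hi = f.min(), f.max()
        if hi > 1.0 or lo < 0.0:
            f = (f - lo) / (hi - lo) if hi > lo else np.zeros_like(f)
    return np.clip(f, 0.0, 1.0)


def preprocess_frame(frame: np.ndarray, params: PreprocParams) -> np.ndarray:
    """Equalize one frame and return it as uint8 spanning [0, 255].

    CLAHE runs on the frame rescaled to [0, 1] (optionally inverted first),
    then the result is min-max stretched to the full 8-bit range.  A constant
    frame carries no contrast to enhance and is returned as mid-gray 128.
    """
    f = _to_unit_float(frame)
    if params.invert:
        f = 1.0 - f
    if f.max() == f.min():
        return np.full(f.shape, 128, dtype=np.uint8)
    eq = exposure.equalize_adapthist(
        f, kernel_size=params.tile_size, clip_limit=params.clip_limit
    )
    lo, hi = eq.min(), eq.max()
    if hi == lo:
        return np.full(f.shape, 128, dtype=np.uint8)
    out = (eq - lo) / (hi - lo) * 255.0
    return np.rint(out).astype(np.uint8)


def preprocess_movie(
    stack: Sequence[np.ndarray] | np.ndarray, params: PreprocParams
) -> np.ndarray:
    """Apply :func:`preprocess_frame` to every frame, order preserved."""
    frames = [np.asarray(f) for f in stack]
    if len(frames) < 2:
        raise ValueError("a movie needs at least 2 frames")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("ragged stack: all frames must share one shape")
    out = np.empty((len(frames),) + shape, dtype=np.uint8)
    for i, f in enumerate(frames):
        out[i] = preprocess_frame(f, params)
        if (i + 1) % 50 == 0 or i + 1 == len(frames):
            log.info("pre-processed %d/%d frames", i + 1, len(frames))
    return out
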