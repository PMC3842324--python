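"""Movie and configuration I/O.

Movies are multi-page grayscale TIFF stacks (8- or 16-bit) or directories of
single-frame images ordered by filename.  Run configurations round-trip
through YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import tifffile
import yaml
from imageio.v3 import imread as _imread

from .kernel import KernelConfig
from .metrics import Calibration
from .preprocess import PreprocParams
from .simulate import SimParams
from .track import TrackerParams

log = logging.getLogger(__name__)

__all__ = ["read_stack", "write_stack", "RunConfig", "load_config", "save_config"]

_FRAME_SUFFIXES = (".tif", ".tiff", ".png")


def read_stack(path: Union[str, Path]) -> np.ndarray:
    """Read a movie as a ``(T, H, W)`` array.

    Accepts a multi-page TIFF or a directory of frames (lexicographic file
    order).  Single-channel only; ragged frame shapes are an error.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not files:
            raise ValueError(f"no frames found in directory {path}")
        frames = [np.asarray(_imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        stack = np.stack(frames)
    else:
        try:
            stack = tifffile.imread(path)
        except Exception as exc:  # unreadable file -> format error with name
            raise ValueError(f"cannot read movie {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(
            f"{path}: expected single-channel frames, got shape {stack.shape}"
        )
    log.info(
        "read %s: %d frames, %dx%d, dtype %s",
        path, stack.shape[0], stack.shape[1], stack.shape[2], stack.dtype,
    )
    return stack


def write_stack(path: Union[str, Path], stack: np.ndarray) -> None:
    """Write a ``(T, H, W)`` (or RGB ``(T, H, W, 3)``) stack as multi-page TIFF."""
    stack = np.asarray(stack)
    if stack.ndim not in (3, 4):
        raise ValueError(f"expected a (T, H, W[, 3]) stack, got shape {stack.shape}")
    tifffile.imwrite(path, stack)


@dataclass
class RunConfig:
    """Every tunable of a run, with documented defaults; YAML round-trips."""

    preproc: PreprocParams = field(default_factory=PreprocParams)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    calibration: Calibration = field(default_factory=Calibration)
    sim: SimParams = field(default_factory=SimParams)
    pause_threshold: float = 0.1  # um/min


def _asdict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["sim"]["image_size"] = list(d["sim"]["image_size"])
    return d


def _fromdict(d: dict) -> RunConfig:
    kernel = KernelConfig(**d["tracker"].pop("kernel"))
    sim = dict(d["sim"])
    sim["image_size"] = tuple(sim["image_size"])
    return RunConfig(
        preproc=PreprocParams(**d["preproc"]),
        tracker=TrackerParams(kernel=kernel, **d["tracker"]),
        calibration=Calibration(**d["calibration"]),
        sim=SimParams(**sim),
        pause_threshold=float(d["pause_threshold"]),
    )


def save_config(path: Union[str, Path], cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(_asdict(cfg), sort_keys=False))


def load_config(path: Union[str, Path]) -> RunConfig:
    return _fromdict(yaml.safe_load(Path(path).read_text()))
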