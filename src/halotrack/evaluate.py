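"""Tracking accuracy against simulator ground truth.

Tracks and truth share the track-table schema and are joined on
``(cell_id, frame)``; accuracy is reported per cell (mean error, RMSE,
completion) and aggregated over the completed tracks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["evaluate_tracks"]


def evaluate_tracks(
    tracks: pd.DataFrame, truth: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Join tracker output with ground truth and measure center errors.

    Returns ``(per_cell, summary)``.  ``per_cell`` has one row per tracked
    cell: points matched, mean/max error, RMSE (pixels) over the tracked
    span, and completion.  ``summary`` aggregates over cells: completion
    percentage and, over completed tracks, the mean of per-cell mean errors
    and the pooled RMSE.
    """
    merged = tracks.merge(
        truth[["cell_id", "frame", "x_px", "y_px"]],
        on=["cell_id", "frame"],
        suffixes=("", "_true"),
    )
    if merged.empty:
        raise ValueError("tracks and truth share no (cell_id, frame) pairs")
    err = np.hypot(
        merged["x_px"] - merged["x_px_true"], merged["y_px"] - merged["y_px_true"]
    )
    merged = merged.assign(err_px=err)

    n_frames = int(truth["frame"].nunique())
    rows = []
    for cell_id, grp in merged.groupby("cell_id", sort=True):
        complete = str(grp["status"].iloc[0]) == "complete" and len(grp) == n_frames
        rows.append(
            {
                "cell_id": int(cell_id),
                "n_points": len(grp),
                "complete": complete,
                "mean_err_px": float(grp["err_px"].mean()),
                "max_err_px": float(grp["err_px"].max()),
                "rmse_px": float(np.sqrt((grp["err_px"] ** 2).mean())),
            }
        )
    per_cell = pd.DataFrame(rows)

    done = per_cell[per_cell["complete"]]
    pooled = merged[merged["cell_id"].isin(done["cell_id"])]
    summary = {
        "n_cells": len(per_cell),
        "n_complete": int(done["complete"].sum()),
        "completion_pct": 100.0 * float(done["complete"].sum()) / len(per_cell),
        "mean_err_px": float(done["mean_err_px"].mean()) if len(done) else float("nan"),
        "rmse_px": float(np.sqrt((pooled["err_px"] ** 2).mean()))
        if len(pooled)
        else float("nan"),
    }
    return per_cell, summary
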