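import numpy as np
import pytest

import halotrack as hk


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def symmetric_cell_frame():
    """One circularly symmetric cell (no deformation, no noise) at an integer
    center, rendered at the simulator's default intensity levels."""
    params = hk.SimParams(
        n_cells=1, n_frames=2, image_size=(128, 128), noise_sd=0.0,
        shape_deform_amp=0.0,
    )
    center = (64.0, 64.0)
    frame = hk.render_frame(np.array([center]), params)
    return frame, center, params


def run_scenario(params: hk.SimParams, tracker: hk.TrackerParams | None = None):
    """Simulate, preprocess and track one scenario; returns everything the
    evaluation needs."""
    tracker = tracker or hk.TrackerParams(kernel=hk.KernelConfig(polarity=params.polarity))
    stack, paths = hk.render_movie(params)
    pre = hk.preprocess_movie(stack, hk.PreprocParams())
    seeds = hk.seed_cells(paths[:, -1, :].tolist(), pre[-1])
    tracks = hk.track_all(seeds, pre, tracker)
    per_cell, summary = hk.evaluate_tracks(
        hk.tracks_to_table(tracks), hk.truth_table(paths)
    )
    return {
        "params": params,
        "stack": stack,
        "paths": paths,
        "pre": pre,
        "tracks": tracks,
        "per_cell": per_cell,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def default_scenario():
    """The simulator's default scenario (10 cells, 100 frames, 512x512,
    2 px/frame, noise SD 8) tracked with the default parameters."""
    return run_scenario(hk.SimParams())
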