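import numpy as np
import pandas as pd
import pytest

from ulmkit.phantom import MBGroundTruth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ground_truth(positions_by_frame, frame_rate_hz=80.0,
                      fov_um=(3200.0, 3200.0)):
    """Build an MBGroundTruth directly from per-frame position lists.

    ``positions_by_frame`` is a list (one entry per frame) of (N, 2) arrays
    of (axial_um, lateral_um).  Velocities are forward differences where a
    bubble id persists, else zero.
    """
    rows = []
    for f, pos in enumerate(positions_by_frame):
        pos = np.atleast_2d(np.asarray(pos, float)) if len(pos) else np.empty((0, 2))
        for b, (ax, la) in enumerate(pos):
            rows.append((f, b, 0, ax, la, 0.0, 0.0, False))
    table = pd.DataFrame(
        rows, columns=["frame", "bubble_id", "segment_id", "axial_um",
                       "lateral_um", "v_axial_mm_s", "v_lateral_mm_s",
                       "respawned"])
    return MBGroundTruth(table, frame_rate_hz, fov_um,
                         n_frames_total=len(positions_by_frame))


@pytest.fixture
def single_bubble_gt():
    """Two frames, one bubble displaced 200 um laterally."""
    return make_ground_truth(
        [[(1600.0, 1500.0)], [(1600.0, 1700.0)]], frame_rate_hz=80.0)
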