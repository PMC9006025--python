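"""Shared fixtures: small deterministic trajectories and sessions."""

import numpy as np
import pytest

from gespeech.io_formats import (
    FINGERTIPS,
    KeypointTrajectory,
    REQUIRED_KEYPOINTS,
)

ALL_KEYPOINT_IDS = np.array(
    sorted(set(REQUIRED_KEYPOINTS["front"]) | {3, 6} | set(FINGERTIPS)), dtype=int
)


def make_trajectory(
    positions_fn=None,
    n_frames: int = 100,
    fps: float = 25.0,
    view: str = "front",
    keypoint_ids=None,
) -> KeypointTrajectory:
    """Build a trajectory from a per-keypoint position function.

    ``positions_fn(kp_id, t)`` returns an (n, 2) array; the default is a
    static standing pose.
    """
    ids = ALL_KEYPOINT_IDS if keypoint_ids is None else np.asarray(keypoint_ids)
    t = np.arange(n_frames) / fps
    base = {
        0: (500.0, 120.0), 1: (500.0, 220.0), 2: (430.0, 230.0), 3: (415.0, 330.0),
        4: (420.0, 430.0), 5: (570.0, 230.0), 6: (585.0, 330.0), 7: (580.0, 430.0),
        8: (500.0, 520.0),
    }
    pos = np.zeros((n_frames, ids.size, 2))
    for i, k in enumerate(ids):
        k = int(k)
        if positions_fn is not None:
            xy = positions_fn(k, t)
            if xy is not None:
                pos[:, i, :] = xy
                continue
        if k in base:
            pos[:, i, :] = base[k]
        else:  # finger tips ride on their hand
            hand = 4 if k >= 30 else 7
            pos[:, i, :] = base[hand]
            pos[:, i, 1] += 18.0
    conf = np.full((n_frames, ids.size), 0.9)
    return KeypointTrajectory(
        fps=fps, view=view, positions=pos, confidence=conf, keypoint_ids=ids
    )


@pytest.fixture
def static_traj():
    return make_trajectory()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
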