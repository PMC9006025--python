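"""Articulator-level motion energy.

Motion energy of an articulator over an event window is the summed
frame-to-frame pixel displacement of its (possibly reference-corrected)
position: ``E = sum_t ||p(t) - p(t-1)||``.  Correcting for a reference
articulator means expressing the target position *relative* to the mean
position of the reference keypoints before differencing, which nulls
motion common to both (e.g. arm energy is zero under pure torso sway).

The fixed correction scheme: head and arms are corrected by the torso,
fingers by the arms, and the torso by nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    FINGERTIPS,
    GestureEvent,
    KeypointTrajectory,
    L_HAND,
    NECK,
    NOSE,
    R_HAND,
    logger,
)

#: articulator -> (target keypoints, reference keypoints or None)
ARTICULATOR_MAP: dict[str, tuple[tuple[int, ...], tuple[int, ...] | None]] = {
    "torso": ((NECK,), None),
    "head": ((NOSE,), (NECK,)),
    "arms": ((R_HAND, L_HAND), (NECK,)),
    "fingers": (FINGERTIPS, (R_HAND, L_HAND)),
}

ARTICULATORS = tuple(ARTICULATOR_MAP)


@dataclass(frozen=True)
class ArticulatorEnergy:
    """Motion energy (px) of one articulator over one event window."""

    articulator: str
    event_ref: str
    energy: float
    corrected_by: str | None

    def __post_init__(self) -> None:
        if self.articulator not in ARTICULATOR_MAP:
            raise ValueError(f"unknown articulator {self.articulator!r}")
        if not (np.isnan(self.energy) or self.energy >= 0):
            raise ValueError("motion energy must be non-negative")


def _mean_position(traj: KeypointTrajectory, keypoints) -> np.ndarray:
    """Per-frame mean position over a keypoint set, NaN-aware."""
    stack = np.stack([traj.xy(k) for k in keypoints], axis=1)  # (T, K, 2)
    with np.errstate(invalid="ignore"):
        return np.nanmean(stack, axis=1)


def relative_trajectory(
    traj: KeypointTrajectory,
    target_keypoints,
    reference_keypoints,
) -> np.ndarray:
    """Target position relative to the mean reference position, per frame.

    Frames where the reference is fully missing come out NaN.  Returns an
    array of shape (frames, 2) holding the *mean* target position minus the
    mean reference position (left/right values averaged, as for arms).
    """
    target = _mean_position(traj, target_keypoints)
    reference = _mean_position(traj, reference_keypoints)
    return target - reference


def _displacement_norm(pos: np.ndarray, metric: str) -> np.ndarray:
    d = np.diff(pos, axis=0)
    if metric == "euclidean":
        return np.hypot(d[:, 0], d[:, 1])
    if metric == "manhattan":
        return np.abs(d).sum(axis=1)
    raise ValueError(f"unknown displacement metric {metric!r}")


def articulator_energy(
    traj: KeypointTrajectory,
    articulator: str,
    window: tuple[float, float],
    metric: str = "euclidean",
) -> ArticulatorEnergy:
    """Motion energy of one articulator over ``window`` (seconds).

    For multi-keypoint articulators the left/right (or finger-tip)
    positions are averaged before differencing.  ``metric`` selects the
    per-frame displacement norm: Euclidean (default) or Manhattan
    ``|dx| + |dy|``.
    """
    targets, refs = ARTICULATOR_MAP[articulator]
    sl = traj.frame_slice(*window)
    if sl.stop - sl.start < 2:
        raise ValueError("energy window must span at least 2 frames")
    if refs is None:
        pos = _mean_position(traj, targets)[sl]
        corrected_by = None
    else:
        pos = relative_trajectory(traj, targets, refs)[sl]
        corrected_by = {"head": "torso", "arms": "torso", "fingers": "arms"}[
            articulator
        ]
    steps = _displacement_norm(pos, metric)
    energy = float(np.nansum(steps)) if np.isfinite(steps).any() else float("nan")
    return ArticulatorEnergy(
        articulator=articulator,
        event_ref=f"{window[0]:.3f}-{window[1]:.3f}",
        energy=energy,
        corrected_by=corrected_by,
    )


def event_energies(
    traj: KeypointTrajectory,
    events: list[GestureEvent],
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Motion energy of every articulator for every gesture event."""
    rows = []
    for ev in events:
        for art in ARTICULATORS:
            e = articulator_energy(traj, art, (ev.start_s, ev.end_s), metric=metric)
            rows.append(
                {
                    "participant": ev.participant_id,
                    "dyad": ev.dyad_id,
                    "grade": ev.blur_grade,
                    "articulator": art,
                    "event_id": ev.event_id,
                    "energy_px": e.energy,
                }
            )
    return pd.DataFrame(rows)


def energy_by_grade(energies: pd.DataFrame, events: list[GestureEvent]) -> pd.DataFrame:
    """Long-format per-participant x grade x articulator energy table.

    One row per event x articulator, keyed for the statistics module.
    Grades with no events simply contribute no rows (logged).
    """
    present = set(energies["grade"].unique())
    all_grades = {ev.blur_grade for ev in events}
    for g in sorted(all_grades - present):
        logger.info("blur grade %d has no usable energy rows", g)
    out = energies.sort_values(
        ["participant", "grade", "articulator", "event_id"]
    ).reset_index(drop=True)
    return out[["participant", "dyad", "grade", "articulator", "event_id", "energy_px"]]
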