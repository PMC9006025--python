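"""Reading, validation and writing of the pipeline's on-disk formats.

The raw material of the analysis is (a) 2-D keypoint trajectories from a
video pose tracker (25 body keypoints plus five finger tips per hand, pixel
units, fixed frame rate), (b) manually annotated gesture events, (c) mono
speech audio and (d) the blur schedule that maps session time onto ten
grades of visual degradation.  This module owns the domain containers and
every parse/validate/serialise step; all downstream modules work on the
in-memory types defined here.

Conventions: time is seconds from session start, frame index 0-based;
pixel origin is top-left with y increasing downward (pose-tracker
convention).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gespeech")

# ---------------------------------------------------------------------------
# Keypoint map (25-point body model + finger tips)
# ---------------------------------------------------------------------------

#: Body keypoint ids used by the analysis (25-keypoint body map).
NOSE = 0          #: head marker
NECK = 1          #: upper torso marker
R_SHOULDER = 2
R_HAND = 4
L_SHOULDER = 5
L_HAND = 7
MID_HIP = 8

#: Finger-tip ids: five per hand, appended after the 25 body keypoints.
LEFT_FINGERTIPS = tuple(range(25, 30))
RIGHT_FINGERTIPS = tuple(range(30, 35))
FINGERTIPS = LEFT_FINGERTIPS + RIGHT_FINGERTIPS

#: Keypoints each camera view must provide.
REQUIRED_KEYPOINTS = {
    "front": (NOSE, NECK, R_SHOULDER, R_HAND, L_SHOULDER, L_HAND, MID_HIP)
    + FINGERTIPS,
    "side": (R_HAND, L_HAND, MID_HIP),
}

GESTURE_TYPES = ("representational", "pragmatic", "interactive", "emblem", "deictic")

#: Default confidence floor below which a tracked point is treated as missing.
DEFAULT_CONFIDENCE_FLOOR = 0.3
#: Longest gap (s) that is bridged by linear interpolation.
DEFAULT_MAX_GAP_S = 0.5


class FormatError(ValueError):
    """Raised when an input file violates the declared format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class KeypointTrajectory:
    """Time-indexed 2-D pixel positions for one camera view.

    Attributes
    ----------
    fps : float
        Frames per second (> 0).
    view : str
        ``"front"`` or ``"side"``.
    positions : ndarray, shape (frames, n_keypoints, 2)
        Pixel coordinates; NaN where the point is unusable.
    confidence : ndarray, shape (frames, n_keypoints)
        Tracker confidence in [0, 1]; 0 marks unusable samples.
    keypoint_ids : ndarray of int
        Integer labels following the 25-keypoint body map plus finger tips.
    """

    fps: float
    view: str
    positions: np.ndarray
    confidence: np.ndarray
    keypoint_ids: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.keypoint_ids = np.asarray(self.keypoint_ids, dtype=int)
        if self.fps <= 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if self.view not in ("front", "side"):
            raise FormatError(f"view must be 'front' or 'side', got {self.view!r}")
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise FormatError("positions must have shape (frames, keypoints, 2)")
        if self.confidence.shape != self.positions.shape[:2]:
            raise FormatError("confidence shape does not match positions")
        if len(self.keypoint_ids) != self.positions.shape[1]:
            raise FormatError("keypoint_ids length does not match positions")
        if len(np.unique(self.keypoint_ids)) != len(self.keypoint_ids):
            raise FormatError("duplicate keypoint ids")
        tracked = self.confidence > 0
        if not np.isfinite(self.positions[tracked]).all():
            raise FormatError("non-finite position with positive confidence")
        self._index = {int(k): i for i, k in enumerate(self.keypoint_ids)}

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.fps

    def has_keypoint(self, keypoint_id: int) -> bool:
        return int(keypoint_id) in self._index

    def xy(self, keypoint_id: int) -> np.ndarray:
        """Positions of one keypoint, shape (frames, 2)."""
        try:
            col = self._index[int(keypoint_id)]
        except KeyError:
            raise FormatError(f"keypoint {keypoint_id} not present") from None
        return self.positions[:, col, :]

    def frame_slice(self, start_s: float, end_s: float) -> slice:
        """Frame-index slice covering [start_s, end_s]."""
        i0 = int(np.floor(start_s * self.fps))
        i1 = int(np.ceil(end_s * self.fps)) + 1
        if i0 < 0 or i1 > self.n_frames:
            raise ValueError(
                f"window [{start_s}, {end_s}] s outside trajectory "
                f"(0, {self.duration_s:.3f}) s"
            )
        return slice(i0, i1)


@dataclass(frozen=True)
class GestureEvent:
    """One annotated gesture interval."""

    start_s: float
    end_s: float
    gesture_type: str
    participant_id: str
    dyad_id: str
    blur_grade: int = 0
    event_id: str = ""

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise FormatError(
                f"gesture end ({self.end_s}) must follow start ({self.start_s})"
            )
        if self.gesture_type not in GESTURE_TYPES:
            raise FormatError(
                f"unknown gesture type {self.gesture_type!r}; "
                f"expected one of {GESTURE_TYPES}"
            )
        if self.blur_grade and not 1 <= self.blur_grade <= 10:
            raise FormatError(f"blur grade {self.blur_grade} outside 1..10")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass(frozen=True)
class BlurSchedule:
    """Stepwise blur manipulation: ``n_grades`` windows of equal duration.

    ``direction="clear_to_blur"`` labels the first window grade 1 (clear) and
    the last grade ``n_grades`` (most blurred); ``"blur_to_clear"`` reverses
    the labels, so grade always means *amount of blur*, not elapsed time.
    """

    grade_duration_s: float = 240.0
    n_grades: int = 10
    direction: str = "clear_to_blur"

    def __post_init__(self) -> None:
        if self.direction not in ("clear_to_blur", "blur_to_clear"):
            raise FormatError(f"unknown schedule direction {self.direction!r}")
        if self.n_grades < 1 or self.grade_duration_s <= 0:
            raise FormatError("schedule must have >= 1 grade of positive duration")

    @property
    def session_duration_s(self) -> float:
        return self.n_grades * self.grade_duration_s

    def grade_of(self, t_s: float | np.ndarray) -> int | np.ndarray:
        """Blur grade at session time ``t_s`` (clipped to the session)."""
        idx = np.floor(np.asarray(t_s, dtype=float) / self.grade_duration_s)
        idx = np.clip(idx, 0, self.n_grades - 1).astype(int)
        if self.direction == "clear_to_blur":
            grade = idx + 1
        else:
            grade = self.n_grades - idx
        return grade if grade.ndim else int(grade)


# ---------------------------------------------------------------------------
# Keypoint files: per-frame JSON dialect and flat CSV
# ---------------------------------------------------------------------------


def _interpolate_low_confidence(
    positions: np.ndarray,
    confidence: np.ndarray,
    fps: float,
    confidence_floor: float,
    max_gap_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mark sub-floor samples missing; linearly bridge short gaps.

    Gaps longer than ``max_gap_s`` remain NaN with confidence 0 (unusable
    segment).  Gap lengths are logged for audit.
    """
    positions = positions.copy()
    confidence = confidence.copy()
    n_frames, n_kp, _ = positions.shape
    max_gap = int(round(max_gap_s * fps))
    t = np.arange(n_frames)
    for k in range(n_kp):
        bad = confidence[:, k] < confidence_floor
        if not bad.any():
            continue
        positions[bad, k, :] = np.nan
        good = ~bad
        if good.sum() < 2:
            confidence[:, k] = 0.0
            continue
        # enumerate contiguous bad runs
        runs = []
        i = 0
        while i < n_frames:
            if bad[i]:
                j = i
                while j < n_frames and bad[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        for i0, i1 in runs:
            gap = i1 - i0
            interior = i0 > 0 and i1 < n_frames
            if interior and gap <= max_gap:
                logger.debug(
                    "interpolating %d-frame gap (%.3f s) in keypoint %d",
                    gap, gap / fps, k,
                )
                for ax in range(2):
                    positions[i0:i1, k, ax] = np.interp(
                        t[i0:i1], t[good], positions[good, k, ax]
                    )
                confidence[i0:i1, k] = confidence_floor
            else:
                logger.info(
                    "keypoint %d unusable for %d frames (%.3f s)", k, gap, gap / fps
                )
                confidence[i0:i1, k] = 0.0
    return positions, confidence


def _validate_required(keypoint_ids: np.ndarray, view: str) -> None:
    missing = sorted(set(REQUIRED_KEYPOINTS[view]) - set(int(k) for k in keypoint_ids))
    if missing:
        raise FormatError(
            f"view {view!r} requires keypoint(s) {missing} which are absent"
        )


def read_keypoints(
    path,
    view: str,
    fps: float | None = None,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> KeypointTrajectory:
    """Read a keypoint file (per-frame JSON dialect or flat CSV).

    Frames whose confidence falls below ``confidence_floor`` are marked
    missing and linearly interpolated when the gap is at most ``max_gap_s``;
    longer gaps are flagged unusable (confidence 0).

    Parameters
    ----------
    path : str or Path
        ``.json`` file (one object per frame with a flat ``[x, y, c] * K``
        array) or ``.csv`` (columns ``frame, x<id>, y<id>, c<id>, ...``).
    view : str
        ``"front"`` or ``"side"``; controls which keypoints are required.
    fps : float, optional
        Required for CSV unless embedded; JSON embeds it.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            doc = json.load(fh)
        file_fps = doc.get("fps", fps)
        if file_fps is None:
            raise FormatError("fps neither embedded in JSON nor supplied")
        keypoint_ids = np.asarray(doc["keypoint_ids"], dtype=int)
        frames = doc["frames"]
        idx = [f["frame"] for f in frames]
        if np.any(np.diff(idx) <= 0):
            raise FormatError("non-monotone frame index in keypoint JSON")
        flat = np.asarray([f["keypoints"] for f in frames], dtype=float)
        if flat.shape[1] != 3 * len(keypoint_ids):
            raise FormatError("keypoint array length does not match keypoint_ids")
        flat = flat.reshape(len(frames), len(keypoint_ids), 3)
        positions = flat[:, :, :2]
        confidence = flat[:, :, 2]
        fps = float(file_fps)
    elif path.endswith(".csv"):
        df = pd.read_csv(path)
        if "fps" in df.columns:
            fps = float(df["fps"].iloc[0])
        if fps is None:
            raise FormatError("fps must be supplied for CSV keypoint files")
        if "frame" not in df.columns:
            raise FormatError("CSV keypoint file lacks a 'frame' column")
        if np.any(np.diff(df["frame"].to_numpy()) <= 0):
            raise FormatError("non-monotone frame index in keypoint CSV")
        keypoint_ids = sorted(
            int(c[1:]) for c in df.columns if c.startswith("x") and c[1:].isdigit()
        )
        keypoint_ids = np.asarray(keypoint_ids, dtype=int)
        positions = np.stack(
            [df[[f"x{k}", f"y{k}"]].to_numpy(dtype=float) for k in keypoint_ids],
            axis=1,
        )
        confidence = np.stack(
            [df[f"c{k}"].to_numpy(dtype=float) for k in keypoint_ids], axis=1
        )
    else:
        raise FormatError(f"unsupported keypoint file extension: {path}")

    _validate_required(keypoint_ids, view)
    positions, confidence = _interpolate_low_confidence(
        positions, confidence, fps, confidence_floor, max_gap_s
    )
    return KeypointTrajectory(
        fps=fps,
        view=view,
        positions=positions,
        confidence=confidence,
        keypoint_ids=keypoint_ids,
    )


def write_keypoints(traj: KeypointTrajectory, path) -> None:
    """Serialise a trajectory to the JSON dialect or flat CSV (by extension)."""
    path = str(path)
    if path.endswith(".json"):
        flat = np.concatenate(
            [traj.positions, traj.confidence[:, :, None]], axis=2
        ).reshape(traj.n_frames, -1)
        doc = {
            "fps": traj.fps,
            "view": traj.view,
            "keypoint_ids": [int(k) for k in traj.keypoint_ids],
            "frames": [
                {"frame": int(i), "keypoints": [round(float(v), 6) for v in row]}
                for i, row in enumerate(flat)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    elif path.endswith(".csv"):
        cols = {"frame": np.arange(traj.n_frames)}
        for j, k in enumerate(traj.keypoint_ids):
            cols[f"x{k}"] = np.round(traj.positions[:, j, 0], 6)
            cols[f"y{k}"] = np.round(traj.positions[:, j, 1], 6)
            cols[f"c{k}"] = np.round(traj.confidence[:, j], 6)
        df = pd.DataFrame(cols)
        df.insert(1, "fps", traj.fps)
        df.to_csv(path, index=False)
    else:
        raise FormatError(f"unsupported keypoint file extension: {path}")


# ---------------------------------------------------------------------------
# Gesture annotations (ELAN-export-like TSV)
# ---------------------------------------------------------------------------


def read_annotations(path, schedule: BlurSchedule) -> list[GestureEvent]:
    """Read a gesture-annotation TSV and assign blur grades.

    Expects columns ``start``, ``end``, ``type``, ``participant``, ``dyad``
    (seconds for the time columns).  Events are returned sorted by start
    time; each event's blur grade is looked up from ``schedule`` at the
    event *midpoint*, so an event straddling a grade boundary is assigned
    to the grade containing its centre.  Overlapping events for one
    participant are kept but provoke a warning.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"start", "end", "type", "participant", "dyad"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"annotation TSV lacks column(s) {sorted(required - set(df.columns))}"
        )
    events = []
    for i, row in df.iterrows():
        ev = GestureEvent(
            start_s=float(row["start"]),
            end_s=float(row["end"]),
            gesture_type=str(row["type"]),
            participant_id=str(row["participant"]),
            dyad_id=str(row["dyad"]),
            event_id=str(row["event_id"]) if "event_id" in df.columns else f"ev{i:05d}",
        )
        ev = GestureEvent(
            **{**ev.__dict__, "blur_grade": int(schedule.grade_of(ev.midpoint_s))}
        )
        events.append(ev)
    events.sort(key=lambda e: e.start_s)
    by_participant: dict[str, list[GestureEvent]] = {}
    for ev in events:
        by_participant.setdefault(ev.participant_id, []).append(ev)
    for pid, evs in by_participant.items():
        for a, b in zip(evs, evs[1:]):
            if b.start_s < a.end_s:
                warnings.warn(
                    f"overlapping gestures for participant {pid}: "
                    f"[{a.start_s:.2f},{a.end_s:.2f}] and "
                    f"[{b.start_s:.2f},{b.end_s:.2f}] (both kept)",
                    stacklevel=2,
                )
    return events


def write_annotations(events: list[GestureEvent], path) -> None:
    """Write events back to the annotation TSV (round-trip counterpart)."""
    df = pd.DataFrame(
        {
            "start": [e.start_s for e in events],
            "end": [e.end_s for e in events],
            "type": [e.gesture_type for e in events],
            "participant": [e.participant_id for e in events],
            "dyad": [e.dyad_id for e in events],
            "event_id": [e.event_id for e in events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Modality split
# ---------------------------------------------------------------------------

MODALITY_NONE = ""
SPEECH_ONLY = "speech_only"
SPEECH_WITH_GESTURE = "speech_with_gesture"


def assign_modality(
    times: np.ndarray,
    voiced_intervals,
    events: list[GestureEvent],
    participant_id: str | None = None,
    max_drift_s: float = 0.0,
) -> np.ndarray:
    """Label each voiced sample speech-with-gesture or speech-only.

    A voiced sample is ``speech_with_gesture`` when it falls inside any
    gesture event of the same participant, else ``speech_only``; unvoiced
    samples get the empty label.  ``voiced_intervals`` is a sequence of
    ``(start_s, end_s)`` pairs on the same clock as ``times``.

    ``max_drift_s`` declares the tolerated clock offset between the audio
    and annotation streams; intervals starting before ``-max_drift_s`` or
    ending after the last sample plus ``max_drift_s`` indicate a clock
    mismatch and raise.
    """
    times = np.asarray(times, dtype=float)
    t_end = times[-1] if times.size else 0.0
    voiced = np.zeros(times.shape, dtype=bool)
    for v0, v1 in voiced_intervals:
        if v0 < -max_drift_s - 1e-9 or v1 > t_end + max_drift_s + 1e-9:
            raise ValueError(
                f"voiced interval [{v0}, {v1}] outside sample clock "
                f"[0, {t_end:.3f}] (+/- {max_drift_s} s drift allowance)"
            )
        voiced |= (times >= v0) & (times <= v1)
    gestured = np.zeros(times.shape, dtype=bool)
    for ev in events:
        if participant_id is not None and ev.participant_id != participant_id:
            continue
        gestured |= (times >= ev.start_s) & (times <= ev.end_s)
    labels = np.full(times.shape, MODALITY_NONE, dtype=object)
    labels[voiced & gestured] = SPEECH_WITH_GESTURE
    labels[voiced & ~gestured] = SPEECH_ONLY
    return labels


# ---------------------------------------------------------------------------
# Config + tidy outputs
# ---------------------------------------------------------------------------


def read_config(path) -> dict:
    """Load the YAML run configuration as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy analysis table as CSV (the single output format)."""
    df.to_csv(path, index=False)
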