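"""Signal-level gesture kinematics.

Per-gesture features computed from the hand trajectories (keypoints 4 and
7, front view unless stated):

* **peak velocity** — maximum of the smoothed two-hand speed profile (px/s);
* **submovements** — number of ballistic velocity pulses (strokes,
  repetitions, preparations) separated by clear velocity valleys;
* **hold-time** — cumulative stillness between first movement onset and
  last movement offset (pre- and post-gesture rest excluded);
* **size** — x-extent x y-extent of the union of both hands' positions
  relative to the upper torso (px^2);
* **McNeillian space** — ordinal gesture-space category (centre-centre <
  centre < periphery < extra-periphery) of the most extreme region either
  hand reaches, in a body-normalised frame;
* **depth** — side-view extremum of the horizontal hands-to-hips distance;
* **nPVI** — normalised pairwise variability of submovement durations;
* **gesture rate** — gestures per minute per blur grade.

Positions are low-pass filtered before differentiation; all thresholds are
parameters of the relevant function with defaults declared below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import (
    BlurSchedule,
    GestureEvent,
    KeypointTrajectory,
    L_HAND,
    L_SHOULDER,
    MID_HIP,
    NECK,
    R_HAND,
    R_SHOULDER,
)

# -- default thresholds (all configurable per call) -------------------------

#: cutoff (Hz) of the 3rd-order Butterworth position filter
SMOOTH_CUTOFF_HZ = 10.0
#: submovement peaks must exceed this fraction of the event peak speed
MOVEMENT_THRESHOLD_FRAC = 0.15
#: two peaks are distinct submovements only if the valley between them is
#: below this fraction of the smaller peak
VALLEY_FRACTION = 0.5
#: a hold requires speed below this fraction of event peak speed ...
STILLNESS_FRAC = 0.10
#: ... for at least this long (s)
MIN_HOLD_S = 0.2

SPACE_CATEGORIES = ("centre-centre", "centre", "periphery", "extra-periphery")


@dataclass
class KinematicProfile:
    """Feature vector for one gesture event (missing features are NaN)."""

    event_ref: str
    peak_velocity: float = np.nan      # px/s
    submovements: int = 0
    hold_time: float = np.nan          # s
    size: float = np.nan               # px^2
    mcneillian_space: str | None = None
    depth: float = np.nan              # px (side view)
    npvi: float = np.nan

    def as_row(self) -> dict:
        return {
            "event_id": self.event_ref,
            "peak_velocity": self.peak_velocity,
            "submovements": self.submovements,
            "hold_time": self.hold_time,
            "size": self.size,
            "mcneillian_space": self.mcneillian_space,
            "depth": self.depth,
            "npvi": self.npvi,
        }


# ---------------------------------------------------------------------------
# Velocity
# ---------------------------------------------------------------------------


def _smooth_positions(pos: np.ndarray, fps: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth low-pass along the time axis."""
    if cutoff_hz <= 0 or cutoff_hz >= 0.5 * fps:
        return pos
    # filtfilt needs > 3 * (order+1) samples; fall back to raw positions
    if pos.shape[0] <= 15:
        return pos
    b, a = signal.butter(3, cutoff_hz / (0.5 * fps))
    out = pos.copy()
    ok = np.isfinite(pos).all(axis=1)
    if ok.sum() > 15:
        out[ok] = signal.filtfilt(b, a, pos[ok], axis=0)
    return out


def velocity_profile(
    traj: KeypointTrajectory,
    event: GestureEvent,
    smooth_cutoff_hz: float = SMOOTH_CUTOFF_HZ,
) -> dict[str, np.ndarray]:
    """Frame-by-frame hand speed (px/s) over the event window.

    Returns per-hand speed series and their average under keys ``"right"``,
    ``"left"`` and ``"mean"``, plus the frame ``"times"``.  Speed is the
    Euclidean displacement of the smoothed position times fps; the profile
    has one fewer sample than the window has frames, timestamped at the
    trailing frame.
    """
    sl = traj.frame_slice(event.start_s, event.end_s)
    out: dict[str, np.ndarray] = {}
    for name, kp in (("right", R_HAND), ("left", L_HAND)):
        pos = _smooth_positions(traj.xy(kp)[sl], traj.fps, smooth_cutoff_hz)
        d = np.diff(pos, axis=0)
        out[name] = np.hypot(d[:, 0], d[:, 1]) * traj.fps
    out["mean"] = 0.5 * (out["right"] + out["left"])
    out["times"] = traj.times[sl][1:]
    return out


def peak_velocity(profile: np.ndarray) -> float:
    """Maximum speed (px/s) of a velocity profile."""
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty velocity profile")
    return float(np.nanmax(profile))


# ---------------------------------------------------------------------------
# Submovements and holds
# ---------------------------------------------------------------------------


@dataclass
class Submovements:
    """Detected ballistic movement units within one velocity profile."""

    count: int
    peak_indices: np.ndarray
    boundaries: np.ndarray  # sample indices of inter-pulse minima
    onset: int              # first sample above the movement threshold
    offset: int             # last sample above the movement threshold
    durations_s: np.ndarray = field(default_factory=lambda: np.array([]))


def detect_submovements(
    profile: np.ndarray,
    fps: float,
    movement_frac: float = MOVEMENT_THRESHOLD_FRAC,
    valley_fraction: float = VALLEY_FRACTION,
) -> Submovements:
    """Count ballistic velocity pulses in a speed profile.

    A submovement is a velocity peak above ``movement_frac`` x the event
    peak speed; two adjacent peaks count separately only when the minimum
    between them drops below ``valley_fraction`` x the smaller of the two
    peaks — otherwise they are merged into one pulse (keeping the higher
    peak).  Boundaries are placed at the separating minima.

    The speed profile gets a light 3-sample moving average and peaks must
    also be *prominent* by the movement threshold, which rejects
    single-frame tracker-noise spikes without touching genuine ballistic
    pulses (which rise from near zero).
    """
    v = np.asarray(profile, dtype=float)
    v = np.where(np.isfinite(v), v, 0.0)
    if v.size >= 3:
        v = np.convolve(v, np.ones(3) / 3.0, mode="same")
    if v.size == 0 or np.nanmax(v) <= 0:
        return Submovements(0, np.array([], int), np.array([], int), 0, 0)
    vmax = float(np.max(v))
    thresh = movement_frac * vmax
    peaks, _ = signal.find_peaks(v, height=thresh, prominence=thresh)
    # profile edges can hold the true extremum of a truncated pulse
    if v[0] > thresh and (v.size < 2 or v[0] >= v[1]):
        peaks = np.concatenate(([0], peaks))
    if v[-1] > thresh and v[-1] >= v[-2]:
        peaks = np.concatenate((peaks, [v.size - 1]))
    peaks = np.unique(peaks)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(v))])
    # merge peaks not separated by a deep enough valley
    kept = [int(peaks[0])]
    boundaries: list[int] = []
    for p in peaks[1:]:
        p = int(p)
        lo = kept[-1]
        valley_idx = lo + int(np.argmin(v[lo : p + 1]))
        valley = v[valley_idx]
        if valley < valley_fraction * min(v[lo], v[p]):
            kept.append(p)
            boundaries.append(valley_idx)
        elif v[p] > v[lo]:
            kept[-1] = p
    above = np.flatnonzero(v > thresh)
    onset, offset = int(above[0]), int(above[-1])
    edges = np.concatenate(([onset], boundaries, [offset]))
    durations = np.diff(edges) / fps
    return Submovements(
        count=len(kept),
        peak_indices=np.asarray(kept, int),
        boundaries=np.asarray(boundaries, int),
        onset=onset,
        offset=offset,
        durations_s=durations,
    )


def hold_time(
    profile: np.ndarray,
    fps: float,
    movement_frac: float = MOVEMENT_THRESHOLD_FRAC,
    stillness_frac: float = STILLNESS_FRAC,
    min_hold_s: float = MIN_HOLD_S,
) -> float:
    """Cumulative stillness (s) within the executed part of a gesture.

    Only stillness between the first movement onset and the last movement
    offset counts — rest before the gesture starts and after it ends is
    excluded.  A still stretch qualifies as a hold when speed stays below
    ``stillness_frac`` x event peak speed for at least ``min_hold_s``.
    Hold boundaries are located by linear interpolation of the speed
    profile at the stillness threshold, so holds are measured with
    sub-frame resolution.
    """
    v = np.asarray(profile, dtype=float)
    v = np.where(np.isfinite(v), v, 0.0)
    if v.size == 0 or np.max(v) <= 0:
        return 0.0
    if v.size >= 3:  # mirror the submovement detector's profile smoothing
        v = np.convolve(v, np.ones(3) / 3.0, mode="same")
    sub = detect_submovements(profile, fps, movement_frac)
    thr = stillness_frac * float(np.max(v))
    total = 0.0
    i = sub.onset
    while i <= sub.offset:
        if v[i] < thr:
            j = i
            while j <= sub.offset and v[j] < thr:
                j += 1
            # sub-frame crossing times at both ends of the still run
            start = float(i)
            if i > sub.onset and v[i - 1] > v[i]:
                start = i - 1 + (v[i - 1] - thr) / (v[i - 1] - v[i])
            end = float(j - 1)
            if j <= sub.offset and v[j] > v[j - 1]:
                end = j - 1 + (thr - v[j - 1]) / (v[j] - v[j - 1])
            dur = (end - start) / fps
            if dur >= min_hold_s:
                total += dur
            i = j
        else:
            i += 1
    return total


# ---------------------------------------------------------------------------
# Spatial features
# ---------------------------------------------------------------------------


def gesture_size(traj: KeypointTrajectory, event: GestureEvent) -> dict:
    """Volumetric gesture size: x-extent x y-extent (px^2), front view.

    Extents are of the union of both hands' positions over the event,
    expressed relative to the upper-torso keypoint so body translation
    does not inflate the box.
    """
    sl = traj.frame_slice(event.start_s, event.end_s)
    torso = traj.xy(NECK)[sl]
    pts = np.concatenate([traj.xy(R_HAND)[sl] - torso, traj.xy(L_HAND)[sl] - torso])
    pts = pts[np.isfinite(pts).all(axis=1)]
    if pts.shape[0] == 0:
        return {"size": np.nan, "x_extent": np.nan, "y_extent": np.nan}
    x_ext = float(np.ptp(pts[:, 0]))
    y_ext = float(np.ptp(pts[:, 1]))
    return {"size": x_ext * y_ext, "x_extent": x_ext, "y_extent": y_ext}


@dataclass(frozen=True)
class BodyFrame:
    """Body-centred reference geometry for gesture-space categorisation."""

    sternum: np.ndarray       # (x, y) px
    shoulder_width: float     # px
    neck_to_hip: float        # px
    head_y: float             # top of head (px, image coordinates)
    hip_y: float
    shoulder_xs: tuple[float, float]


def body_frame(traj: KeypointTrajectory, sl: slice) -> BodyFrame:
    """Derive the gesture-space frame from shoulders, neck and hips."""
    med = {}
    for kp in (NECK, MID_HIP, R_SHOULDER, L_SHOULDER):
        if not traj.has_keypoint(kp):
            raise ValueError(f"body frame needs keypoint {kp}")
        xy = traj.xy(kp)[sl]
        xy = xy[np.isfinite(xy).all(axis=1)]
        if xy.shape[0] == 0:
            raise ValueError(f"body frame undeterminable: keypoint {kp} missing")
        med[kp] = np.median(xy, axis=0)
    neck, hip = med[NECK], med[MID_HIP]
    shoulder_width = float(abs(med[R_SHOULDER][0] - med[L_SHOULDER][0]))
    neck_to_hip = float(abs(hip[1] - neck[1]))
    sternum = np.array([neck[0], neck[1] + 0.25 * neck_to_hip])
    # head top approximated one quarter of the torso height above the neck
    head_y = float(neck[1] - 0.5 * neck_to_hip)
    if shoulder_width <= 0 or neck_to_hip <= 0:
        raise ValueError("degenerate body frame (zero shoulder width or torso)")
    return BodyFrame(
        sternum=sternum,
        shoulder_width=shoulder_width,
        neck_to_hip=neck_to_hip,
        head_y=head_y,
        hip_y=float(hip[1]),
        shoulder_xs=(float(med[R_SHOULDER][0]), float(med[L_SHOULDER][0])),
    )


def _space_of_point(p: np.ndarray, frame: BodyFrame) -> int:
    """Ordinal space index of one hand position (0 = centre-centre).

    Concentric-box scheme: centre-centre spans sternum +/- 0.25 shoulder
    widths horizontally and +/- 0.25 neck-to-hip vertically; centre is
    twice that box; periphery is the box bounded by the shoulders, head
    top and hips; beyond is extra-periphery.  Points exactly on a boundary
    go to the *outer* region.
    """
    dx = abs(p[0] - frame.sternum[0])
    dy = abs(p[1] - frame.sternum[1])
    hw, hh = 0.25 * frame.shoulder_width, 0.25 * frame.neck_to_hip
    if dx < hw and dy < hh:
        return 0
    if dx < 2 * hw and dy < 2 * hh:
        return 1
    x_lo = min(frame.shoulder_xs) - 0.5 * frame.shoulder_width
    x_hi = max(frame.shoulder_xs) + 0.5 * frame.shoulder_width
    if x_lo < p[0] < x_hi and frame.head_y < p[1] < frame.hip_y:
        return 2
    return 3


def mcneillian_space(
    traj: KeypointTrajectory, event: GestureEvent, frame: BodyFrame | None = None
) -> str:
    """Most extreme gesture-space region reached by either hand.

    The per-event summary is the outermost category visited, matching a
    one-category-per-gesture reading of peripheral space use.
    """
    sl = traj.frame_slice(event.start_s, event.end_s)
    if frame is None:
        frame = body_frame(traj, sl)
    worst = 0
    for kp in (R_HAND, L_HAND):
        for p in traj.xy(kp)[sl]:
            if np.isfinite(p).all():
                worst = max(worst, _space_of_point(p, frame))
    return SPACE_CATEGORIES[worst]


def gesture_depth(side_traj: KeypointTrajectory | None, event: GestureEvent) -> float:
    """Side-view depth: event maximum of |hands - hips| horizontal distance.

    Uses the two-hand mean position against the hip keypoint.  Returns NaN
    (feature absent, not zero) when no side view is available.
    """
    if side_traj is None:
        return np.nan
    sl = side_traj.frame_slice(event.start_s, event.end_s)
    hands = 0.5 * (side_traj.xy(R_HAND)[sl] + side_traj.xy(L_HAND)[sl])
    hips = side_traj.xy(MID_HIP)[sl]
    d = np.abs(hands[:, 0] - hips[:, 0])
    d = d[np.isfinite(d)]
    return float(np.max(d)) if d.size else np.nan


# ---------------------------------------------------------------------------
# Temporal variability, rate, collinearity
# ---------------------------------------------------------------------------


def npvi(durations) -> float:
    """Normalised pairwise variability index of successive durations.

    ``100/(m-1) * sum |d_k - d_{k+1}| / ((d_k + d_{k+1})/2)`` — order
    sensitive and unitless.  Undefined (NaN) for fewer than two durations.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 2:
        return np.nan
    num = np.abs(np.diff(d))
    den = 0.5 * (d[:-1] + d[1:])
    return float(100.0 / (d.size - 1) * np.sum(num / den))


def gesture_rate(events: list[GestureEvent], schedule: BlurSchedule) -> pd.DataFrame:
    """Gestures per minute per participant x blur grade (zeros included)."""
    participants = sorted({(e.participant_id, e.dyad_id) for e in events})
    rows = []
    minutes = schedule.grade_duration_s / 60.0
    for pid, dyad in participants:
        for grade in range(1, schedule.n_grades + 1):
            n = sum(
                1
                for e in events
                if e.participant_id == pid and e.blur_grade == grade
            )
            rows.append(
                {
                    "participant": pid,
                    "dyad": dyad,
                    "grade": grade,
                    "rate_per_min": n / minutes,
                }
            )
    return pd.DataFrame(rows)


def vif_screen(feature_table: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Variance inflation factor of each numeric feature against the rest.

    ``VIF_j = 1 / (1 - R^2_j)`` from an OLS regression of feature j on the
    other features (with intercept).  Perfect collinearity yields an
    infinite VIF, reported and flagged.  Rows with any missing value are
    dropped listwise first.
    """
    import statsmodels.api as sm

    num = feature_table.select_dtypes(include=[np.number]).dropna()
    cols = list(num.columns)
    if len(cols) < 2:
        raise ValueError("VIF screen needs at least two numeric features")
    if num.shape[0] <= len(cols):
        raise ValueError("VIF screen needs more rows than features")
    rows = []
    for j, col in enumerate(cols):
        y = num[col].to_numpy(dtype=float)
        X = sm.add_constant(num.drop(columns=[col]).to_numpy(dtype=float))
        r2 = sm.OLS(y, X).fit().rsquared
        vif = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"feature": col, "vif": vif, "flagged": bool(vif > threshold)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-event profile assembly
# ---------------------------------------------------------------------------


def profile_event(
    front: KeypointTrajectory,
    event: GestureEvent,
    side: KeypointTrajectory | None = None,
    smooth_cutoff_hz: float = SMOOTH_CUTOFF_HZ,
) -> KinematicProfile:
    """Compute the full kinematic feature vector for one gesture event."""
    vel = velocity_profile(front, event, smooth_cutoff_hz)["mean"]
    sub = detect_submovements(vel, front.fps)
    size = gesture_size(front, event)
    return KinematicProfile(
        event_ref=event.event_id,
        peak_velocity=peak_velocity(vel) if vel.size else np.nan,
        submovements=sub.count,
        hold_time=hold_time(vel, front.fps),
        size=size["size"],
        mcneillian_space=mcneillian_space(front, event),
        depth=gesture_depth(side, event),
        npvi=npvi(sub.durations_s),
    )


def feature_table(
    front: KeypointTrajectory,
    events: list[GestureEvent],
    side: KeypointTrajectory | None = None,
) -> pd.DataFrame:
    """Tidy per-gesture feature table (one row per event)."""
    rows = []
    for ev in events:
        prof = profile_event(front, ev, side)
        row = prof.as_row()
        row.update(
            participant=ev.participant_id,
            dyad=ev.dyad_id,
            grade=ev.blur_grade,
            gesture_type=ev.gesture_type,
        )
        rows.append(row)
    return pd.DataFrame(rows)
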