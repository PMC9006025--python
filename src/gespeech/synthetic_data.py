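"""Synthetic dyadic sessions with known ground truth.

The study's raw recordings are not redistributable, so every pipeline
stage is exercised on synthetic sessions that emulate their structure:

* gestures are sequences of **minimum-jerk** hand pulses — the standard
  ballistic motor primitive — so submovement count, inter-pulse stillness
  (hold-time), peak velocity (``1.875 * A / T`` for amplitude ``A`` and
  pulse duration ``T``) and spatial extent are all analytic;
* blur-grade effects enter as quadratic (inverted-U) multipliers on the
  kinematic features and speech intensity, with a linear decrease for
  depth, mirroring the direction of the reported adaptations;
* dyad, participant and gesture-type random effects perturb every feature
  on the log scale;
* the speech envelope is a syllabic (~4 Hz) oscillation that is
  cross-coupled to hand speed during gestures at a configurable lag, and
  the intensity / F0 series carry modality offsets (speech-with-gesture
  vs speech-only).

Defaults reproduce the study scale: 20 dyads (40 participants), 10 blur
grades of 240 s, 25 fps front+side tracking, overall gesture rate around
2.2 gestures/min with type-specific mean durations between 1.7 and 2.8 s.
All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import acoustics as ac
from . import io_formats as iof
from .io_formats import BlurSchedule, GestureEvent, KeypointTrajectory

# minimum-jerk peak speed factor: max of d/dt [10 t^3 - 15 t^4 + 6 t^5]
MINJERK_PEAK_FACTOR = 1.875

#: gesture-type mixture and mean durations (s), following the annotated corpus
GESTURE_TYPE_PROBS = {
    "representational": 0.27,
    "pragmatic": 0.17,
    "interactive": 0.51,
    "emblem": 0.02,
    "deictic": 0.03,
}
GESTURE_TYPE_MEAN_DUR = {
    "representational": 2.8,
    "pragmatic": 1.7,
    "interactive": 1.7,
    "emblem": 2.2,
    "deictic": 1.9,
}


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of a synthetic study.

    Grade effects are multiplicative: a feature with coefficients
    ``(b1, b2)`` is scaled by ``exp(b1*u + b2*(u^2 - mean(u^2)))`` where
    ``u`` maps blur grade onto [-1, 1]; negative ``b2`` gives the
    inverted-U (mid-blur peak) shape, the ``mean(u^2)`` centring keeps the
    session average at the base value.
    """

    n_dyads: int = 20
    n_grades: int = 10
    grade_duration_s: float = 240.0
    direction: str = "clear_to_blur"
    fps: float = 25.0
    envelope_rate_hz: float = 100.0
    seed: int = 0

    # gesture process
    base_rate_per_min: float = 2.2
    rate_effect: tuple[float, float] = (0.0, -0.35)

    # per-feature grade-effect shapes (b1 linear, b2 quadratic, log scale)
    effect_shapes: dict = field(
        default_factory=lambda: {
            "size": (0.0, -0.40),
            "peak_velocity": (0.0, -0.30),
            "hold_time": (0.0, -0.50),
            "depth": (-0.15, 0.0),
            "submovements": (0.0, 0.0),
            "npvi": (0.0, 0.0),
        }
    )

    # base feature values (no blur, average participant)
    base_size_px2: float = 20000.0
    base_pulse_amp_px: float = 120.0
    base_pulse_dur_s: float = 0.45
    base_hold_s: float = 0.45
    base_depth_px: float = 80.0
    mean_submovements: float = 2.4

    # speech / acoustics
    base_intensity_db: float = 62.0
    modality_intensity_offset_db: float = 4.36
    intensity_grade_effect_db: tuple[float, float] = (0.3, -0.6)
    intensity_interaction_db: tuple[float, float] = (1.2, -1.0)
    base_f0_hz: float = 180.0
    modality_f0_offset_hz: float = 3.71
    coupling_lag_ms: float = 50.0
    coupling_strength: float = 0.8
    syllable_rate_hz: float = 4.0
    speech_fraction: float = 0.55

    # random-effect SDs (log scale for kinematics; dB / Hz for acoustics)
    dyad_sd: float = 0.08
    participant_sd: float = 0.12
    gesture_type_sd: float = 0.15
    noise_sd: dict = field(
        default_factory=lambda: {
            "size": 0.50,
            "peak_velocity": 0.35,
            "hold_time": 0.60,
            "depth": 0.30,
            "npvi": 0.40,
            "keypoint_px": 0.0,
            "intensity_db": 1.2,
            "f0_hz": 4.0,
            "intensity_cell_db": 0.8,
            "f0_cell_hz": 2.5,
            "intensity_participant_db": 2.0,
            "f0_participant_hz": 15.0,
        }
    )
    torso_sway_px: float = 4.0
    torso_sway_hz: float = 0.15

    emit_trajectories: bool = True

    def __post_init__(self) -> None:
        if self.n_dyads < 1 or self.n_grades < 1:
            raise ValueError("need at least one dyad and one grade")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")
        if self.base_rate_per_min < 0:
            raise ValueError("gesture rate must be non-negative")
        # infeasibility guard: expected gesture time cannot exceed the grade
        mean_dur = float(np.mean(list(GESTURE_TYPE_MEAN_DUR.values())))
        busiest = self.base_rate_per_min * np.exp(
            max(abs(self.rate_effect[0]), abs(self.rate_effect[1]))
        )
        if busiest * mean_dur > 55.0:
            raise ValueError("gesture rate x duration leaves no inter-gesture time")

    @property
    def schedule(self) -> BlurSchedule:
        return BlurSchedule(
            grade_duration_s=self.grade_duration_s,
            n_grades=self.n_grades,
            direction=self.direction,
        )

    def grade_u(self, grade) -> np.ndarray:
        """Map blur grade 1..n onto [-1, 1]."""
        g = np.asarray(grade, dtype=float)
        half = (self.n_grades - 1) / 2.0 or 1.0
        return (g - (self.n_grades + 1) / 2.0) / half

    def effect_multiplier(self, feature: str, grade) -> np.ndarray:
        """exp(b1*u + b2*(u^2 - mean(u^2))) for the feature's shape."""
        b1, b2 = self.effect_shapes.get(feature, (0.0, 0.0))
        u = self.grade_u(grade)
        u_all = self.grade_u(np.arange(1, self.n_grades + 1))
        c = float(np.mean(u_all**2))
        return np.exp(b1 * u + b2 * (u**2 - c))

    def gesture_rate_fn(self, grade) -> np.ndarray:
        b1, b2 = self.rate_effect
        u = self.grade_u(grade)
        u_all = self.grade_u(np.arange(1, self.n_grades + 1))
        c = float(np.mean(u_all**2))
        return self.base_rate_per_min * np.exp(b1 * u + b2 * (u**2 - c))


@dataclass
class Session:
    """One participant's synthetic session plus its generating truth."""

    participant_id: str
    dyad_id: str
    front: KeypointTrajectory | None
    side: KeypointTrajectory | None
    events: list[GestureEvent]
    acoustics: ac.AcousticSeries
    voiced_intervals: list[tuple[float, float]]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# gesture anatomy
# ---------------------------------------------------------------------------


def minimum_jerk_displacement(n: int) -> np.ndarray:
    """Normalised minimum-jerk position profile on n samples (0 -> 1)."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _draw_events_for_grade(
    cfg: GeneratorConfig,
    grade: int,
    window: tuple[float, float],
    participant: str,
    dyad: str,
    rng: np.random.Generator,
    start_index: int,
) -> list[GestureEvent]:
    rate = float(cfg.gesture_rate_fn(grade))
    duration_min = (window[1] - window[0]) / 60.0
    n = rng.poisson(rate * duration_min)
    types = list(GESTURE_TYPE_PROBS)
    probs = np.array([GESTURE_TYPE_PROBS[t] for t in types])
    probs = probs / probs.sum()
    events = []
    t = window[0] + float(rng.exponential(3.0))
    for i in range(n):
        gtype = str(rng.choice(types, p=probs))
        dur = float(rng.gamma(6.0, GESTURE_TYPE_MEAN_DUR[gtype] / 6.0))
        dur = max(0.8, min(dur, 8.0))
        if t + dur > window[1] - 1.0:
            break
        events.append(
            GestureEvent(
                start_s=round(t, 3),
                end_s=round(t + dur, 3),
                gesture_type=gtype,
                participant_id=participant,
                dyad_id=dyad,
                blur_grade=grade,
                event_id=f"{participant}_ev{start_index + len(events):04d}",
            )
        )
        # 0.7 s floor keeps the post-gesture retraction clear of the next event
        t = t + dur + 0.7 + float(rng.exponential(max(1.0, 60.0 / rate - dur)))
    return events


def _plan_gesture(
    cfg: GeneratorConfig,
    event: GestureEvent,
    re_mult: dict[str, float],
    rng: np.random.Generator,
) -> dict:
    """Draw the pulse-level anatomy of one gesture and its feature truth."""
    grade = event.blur_grade
    k = int(np.clip(rng.poisson(cfg.mean_submovements - 1) + 1, 1, 5))
    avail = event.duration_s - 0.2
    amp = (
        cfg.base_pulse_amp_px
        * float(cfg.effect_multiplier("size", grade)) ** 0.5
        * re_mult["size"] ** 0.5
        * float(np.exp(rng.normal(0.0, cfg.noise_sd["size"] / 2)))
    )
    hold_total = 0.0
    gaps = np.zeros(max(k - 1, 0))
    if k > 1:
        hold_total = (
            cfg.base_hold_s
            * float(cfg.effect_multiplier("hold_time", grade))
            * re_mult["hold_time"]
            * float(np.exp(rng.normal(0.0, cfg.noise_sd["hold_time"])))
        )
        hold_total = min(hold_total, 0.5 * avail)
        w = rng.dirichlet(np.ones(k - 1))
        gaps = hold_total * w
    pulse_time = max(avail - hold_total, 0.3)
    durs = pulse_time * rng.dirichlet(np.full(k, 8.0))
    durs = np.clip(durs, 0.15, None)
    speed_mult = float(cfg.effect_multiplier("peak_velocity", grade)) * re_mult[
        "peak_velocity"
    ]
    peak_speeds = MINJERK_PEAK_FACTOR * amp * speed_mult / durs
    depth_amp = (
        cfg.base_depth_px
        * float(cfg.effect_multiplier("depth", grade))
        * re_mult["depth"]
        * float(np.exp(rng.normal(0.0, cfg.noise_sd["depth"])))
    )
    return {
        "k": k,
        "amp_px": amp,
        "speed_mult": speed_mult,
        "pulse_durs_s": durs,
        "gaps_s": gaps,
        "hold_s": float(gaps.sum()),
        "peak_speed_px_s": float(peak_speeds.max()),
        "depth_px": depth_amp,
    }


def _render_hand_displacement(
    plan: dict, fps: float, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Scalar displacement along the gesture axis, per frame of the event."""
    disp = np.zeros(n_frames)
    t = 0.0
    pos = 0.0
    direction = 1.0
    for j in range(plan["k"]):
        dur = plan["pulse_durs_s"][j]
        i0 = int(round(t * fps))
        i1 = min(int(round((t + dur) * fps)) + 1, n_frames)
        if i1 - i0 >= 2:
            prof = minimum_jerk_displacement(i1 - i0)
            disp[i0:i1] = pos + direction * plan["amp_px"] * plan["speed_mult"] * prof
            pos = disp[i1 - 1]
            disp[i1:] = pos
        t += dur
        if j < plan["k"] - 1:
            t += plan["gaps_s"][j]
        direction = -direction
    return disp


# ---------------------------------------------------------------------------
# full session synthesis
# ---------------------------------------------------------------------------

# rest-pose keypoint layout (front view, px); image origin top-left
_FRONT_POSE = {
    iof.NOSE: (500.0, 120.0),
    iof.NECK: (500.0, 220.0),
    iof.R_SHOULDER: (430.0, 230.0),
    3: (415.0, 330.0),
    iof.R_HAND: (420.0, 430.0),
    iof.L_SHOULDER: (570.0, 230.0),
    6: (585.0, 330.0),
    iof.L_HAND: (580.0, 430.0),
    iof.MID_HIP: (500.0, 520.0),
}


def _random_effect_multipliers(
    cfg: GeneratorConfig, rng: np.random.Generator, features
) -> dict[str, dict[str, float]]:
    """Log-normal dyad/participant/gesture-type multipliers per feature."""
    out: dict[str, dict[str, float]] = {}
    for level, sd in (
        ("dyad", cfg.dyad_sd),
        ("participant", cfg.participant_sd),
        ("gesture_type", cfg.gesture_type_sd),
    ):
        out[level] = {f: float(np.exp(rng.normal(0.0, sd))) for f in features}
    return out


def _voiced_intervals(
    cfg: GeneratorConfig, duration: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Alternating talk/pause intervals covering ~speech_fraction of time."""
    mean_talk, out, t = 4.0, [], 0.0
    mean_pause = mean_talk * (1 - cfg.speech_fraction) / cfg.speech_fraction
    while t < duration:
        talk = float(rng.exponential(mean_talk)) + 0.5
        end = min(t + talk, duration)
        out.append((round(t, 3), round(end, 3)))
        t = end + float(rng.exponential(mean_pause)) + 0.2
    return out


def generate_session(
    cfg: GeneratorConfig,
    dyad: int,
    member: int,
    seed: int | None = None,
) -> Session:
    """Synthesise one participant's session (trajectories, events, acoustics).

    ``seed`` defaults to a deterministic function of ``cfg.seed``, dyad and
    member, so a study is reproducible session-by-session.
    """
    if seed is None:
        seed = (cfg.seed * 1_000_003 + dyad * 101 + member) % (2**31 - 1)
    rng = np.random.default_rng(seed)
    participant = f"d{dyad:02d}p{member}"
    dyad_id = f"d{dyad:02d}"
    schedule = cfg.schedule
    duration = schedule.session_duration_s
    fps = cfg.fps
    n_frames = int(round(duration * fps))

    features = ["size", "peak_velocity", "hold_time", "depth"]
    re_levels = _random_effect_multipliers(cfg, rng, features)

    # --- gesture events -----------------------------------------------------
    events: list[GestureEvent] = []
    for w in range(cfg.n_grades):
        window = (w * cfg.grade_duration_s, (w + 1) * cfg.grade_duration_s)
        grade = int(schedule.grade_of(window[0] + 0.5 * cfg.grade_duration_s))
        events.extend(
            _draw_events_for_grade(
                cfg, grade, window, participant, dyad_id, rng, len(events)
            )
        )
    events.sort(key=lambda e: e.start_s)

    # --- per-event anatomy + truth ------------------------------------------
    plans, truth_rows = [], []
    for ev in events:
        re_mult = {
            f: re_levels["dyad"][f]
            * re_levels["participant"][f]
            * float(np.exp(rng.normal(0.0, cfg.gesture_type_sd)))
            for f in features
        }
        plan = _plan_gesture(cfg, ev, re_mult, rng)
        plans.append(plan)
        truth_rows.append(
            {
                "event_id": ev.event_id,
                "participant": participant,
                "dyad": dyad_id,
                "grade": ev.blur_grade,
                "gesture_type": ev.gesture_type,
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "true_submovements": plan["k"],
                "true_hold_s": plan["hold_s"],
                "true_peak_speed_px_s": plan["peak_speed_px_s"],
                "true_amp_px": plan["amp_px"] * plan["speed_mult"],
                "true_depth_px": plan["depth_px"],
            }
        )
    truth = pd.DataFrame(truth_rows)

    # --- trajectories --------------------------------------------------------
    front = side = None
    hand_speed = np.zeros(n_frames)
    if cfg.emit_trajectories:
        front, side, hand_speed = _render_trajectories(
            cfg, events, plans, n_frames, rng
        )

    # --- acoustics ------------------------------------------------------------
    voiced = _voiced_intervals(cfg, duration, rng)
    series = _render_acoustics(cfg, events, voiced, duration, hand_speed, rng)

    return Session(
        participant_id=participant,
        dyad_id=dyad_id,
        front=front,
        side=side,
        events=events,
        acoustics=series,
        voiced_intervals=voiced,
        truth=truth,
    )


def _render_trajectories(cfg, events, plans, n_frames, rng):
    fps = cfg.fps
    t = np.arange(n_frames) / fps
    kp_ids = np.array(sorted(_FRONT_POSE) + list(iof.FINGERTIPS), dtype=int)
    n_kp = kp_ids.size
    pos = np.zeros((n_frames, n_kp, 2))
    col = {int(k): i for i, k in enumerate(kp_ids)}
    for k, (x, y) in _FRONT_POSE.items():
        pos[:, col[k], 0] = x
        pos[:, col[k], 1] = y
    for j, k in enumerate(iof.FINGERTIPS):
        hand = iof.R_HAND if k in iof.RIGHT_FINGERTIPS else iof.L_HAND
        pos[:, col[k], :] = pos[:, col[hand], :]
        pos[:, col[k], 0] += (j % 5 - 2) * 4.0
        pos[:, col[k], 1] += 18.0
    # whole-body torso sway (translates every keypoint)
    sway = cfg.torso_sway_px * np.sin(2 * np.pi * cfg.torso_sway_hz * t)
    drift = np.cumsum(rng.normal(0.0, 0.05, n_frames))
    pos[:, :, 0] += (sway + drift)[:, None]
    # head nodding noise on the nose keypoint only
    pos[:, col[iof.NOSE], 1] += 2.0 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 6))

    # gesture pulses on both hands (mirrored x, shared y); each event is
    # followed by a smooth retraction to rest outside the event window
    axis = np.array([0.55, -0.835])  # up and outward, unit norm
    disp_all = np.zeros(n_frames)
    for ev, plan in zip(events, plans):
        i0 = int(round(ev.start_s * fps))
        i1 = min(int(round(ev.end_s * fps)) + 1, n_frames)
        disp = _render_hand_displacement(plan, fps, i1 - i0, rng)
        disp_all[i0:i1] = disp
        final = disp[-1] if disp.size else 0.0
        if abs(final) > 1e-9:
            j0 = min(i1 + 2, n_frames)
            j1 = min(j0 + int(round(0.4 * fps)), n_frames)
            if j1 - j0 >= 2:
                disp_all[i1:j0] = final
                disp_all[j0:j1] = final * (
                    1.0 - minimum_jerk_displacement(j1 - j0)
                )
    for hand, sign in ((iof.R_HAND, -1.0), (iof.L_HAND, 1.0)):
        pos[:, col[hand], 0] += sign * axis[0] * disp_all
        pos[:, col[hand], 1] += axis[1] * disp_all
        for k in (
            iof.RIGHT_FINGERTIPS if hand == iof.R_HAND else iof.LEFT_FINGERTIPS
        ):
            pos[:, col[k], 0] += sign * axis[0] * disp_all
            pos[:, col[k], 1] += axis[1] * disp_all
    hand_speed = np.zeros(n_frames)
    hand_speed[1:] = np.abs(np.diff(disp_all)) * fps

    px_noise = cfg.noise_sd.get("keypoint_px", 0.0)
    if px_noise > 0:
        pos = pos + rng.normal(0.0, px_noise, pos.shape)
    conf = np.full((n_frames, n_kp), 0.9)
    front = KeypointTrajectory(
        fps=fps, view="front", positions=pos, confidence=conf, keypoint_ids=kp_ids
    )

    # side view: x encodes depth (distance from hip plane)
    side_ids = np.array([iof.R_HAND, iof.L_HAND, iof.MID_HIP], dtype=int)
    spos = np.zeros((n_frames, 3, 2))
    spos[:, 2, 0] = 300.0
    spos[:, 2, 1] = 520.0
    spos[:, 0, 1] = 430.0
    spos[:, 1, 1] = 430.0
    reach = np.zeros(n_frames)
    for ev, plan in zip(events, plans):
        i0 = int(round(ev.start_s * fps))
        i1 = min(int(round(ev.end_s * fps)) + 1, n_frames)
        if i1 - i0 < 4:
            continue
        prof = np.sin(np.linspace(0.0, np.pi, i1 - i0)) ** 2
        reach[i0:i1] = plan["depth_px"] * prof
    spos[:, 0, 0] = 300.0 + reach
    spos[:, 1, 0] = 300.0 + reach
    if px_noise > 0:
        spos = spos + rng.normal(0.0, px_noise, spos.shape)
    side = KeypointTrajectory(
        fps=cfg.fps,
        view="side",
        positions=spos,
        confidence=np.full((n_frames, 3), 0.9),
        keypoint_ids=side_ids,
    )
    return front, side, hand_speed


def _render_acoustics(cfg, events, voiced, duration, hand_speed, rng):
    """Envelope / intensity / F0 series with modality and grade effects."""
    rate = cfg.envelope_rate_hz
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    schedule = cfg.schedule
    grades = np.asarray(schedule.grade_of(t))
    u_all = cfg.grade_u(np.arange(1, cfg.n_grades + 1))
    # orthonormal linear/quadratic contrasts over the grade values
    P = np.stack([u_all, u_all**2 - np.mean(u_all**2)])
    P = P / np.linalg.norm(P, axis=1, keepdims=True)
    p1, p2 = P[0][grades - 1], P[1][grades - 1]

    gestured = np.zeros(n, dtype=bool)
    for ev in events:
        gestured |= (t >= ev.start_s) & (t <= ev.end_s)
    voiced_mask = np.zeros(n, dtype=bool)
    for v0, v1 in voiced:
        voiced_mask |= (t >= v0) & (t <= v1)

    # envelope: syllabic oscillation, cross-coupled to hand speed in gestures
    phase = np.cumsum(
        2 * np.pi * (cfg.syllable_rate_hz + rng.normal(0.0, 0.2, n)) / rate
    )
    env = 0.45 + 0.30 * np.sin(phase)
    if hand_speed.size > 1 and hand_speed.max() > 0:
        fps_t = np.arange(hand_speed.size) / cfg.fps
        # positive lag = speech leads: envelope now mirrors speed later
        lag = cfg.coupling_lag_ms / 1000.0
        speed_late = np.interp(t + lag, fps_t, hand_speed, left=0.0, right=0.0)
        norm = speed_late / max(speed_late.max(), 1e-9)
        env = env + cfg.coupling_strength * norm * gestured
    env = np.clip(env + rng.normal(0.0, 0.02, n), 0.0, None)
    env[~voiced_mask] *= 0.05

    # participant-level acoustic random effects
    base_int = cfg.base_intensity_db + rng.normal(
        0.0, cfg.noise_sd["intensity_participant_db"]
    )
    base_f0 = cfg.base_f0_hz + rng.normal(0.0, cfg.noise_sd["f0_participant_hz"])

    gi1, gi2 = cfg.intensity_grade_effect_db
    ci1, ci2 = cfg.intensity_interaction_db
    inten = (
        base_int
        + cfg.modality_intensity_offset_db * gestured
        + gi1 * p1
        + gi2 * p2
        + (ci1 * p1 + ci2 * p2) * gestured
    )
    f0 = base_f0 + cfg.modality_f0_offset_hz * gestured

    # content variability: one draw per (grade, modality) cell
    for g in range(1, cfg.n_grades + 1):
        for mod in (False, True):
            sel = (grades == g) & (gestured == mod)
            inten[sel] += rng.normal(0.0, cfg.noise_sd["intensity_cell_db"])
            f0[sel] += rng.normal(0.0, cfg.noise_sd["f0_cell_hz"])
    inten = inten + rng.normal(0.0, cfg.noise_sd["intensity_db"], n)
    f0 = f0 + rng.normal(0.0, cfg.noise_sd["f0_hz"], n)
    f0[~voiced_mask] = np.nan
    inten[~voiced_mask] = -np.inf

    return ac.AcousticSeries(times=t, envelope=env, intensity_db=inten, f0_hz=f0)


def synthesize_voice(
    f0_hz,
    duration_s: float,
    rate: float = 16000.0,
    amplitude=0.3,
    seed: int | None = None,
) -> np.ndarray:
    """Glottal-pulse-train speech stand-in with an exactly known F0 curve.

    ``f0_hz`` may be a scalar or a ``(times, values)`` pair (linearly
    interpolated); ``amplitude`` likewise scalar or time-varying.  The
    waveform is an impulse train at the instantaneous F0 convolved with a
    decaying-exponential glottal kernel, which gives the strong periodic
    autocorrelation structure a pitch tracker expects.  Intended for
    short test windows; study-scale runs use the direct acoustic series.
    """
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    if np.isscalar(f0_hz):
        f0 = np.full(n, float(f0_hz))
    else:
        ft, fv = f0_hz
        f0 = np.interp(t, ft, fv)
    phase = np.cumsum(f0) / rate
    pulses = np.zeros(n)
    pulses[1:] = np.floor(phase[1:]) > np.floor(phase[:-1])
    kernel_t = np.arange(int(0.004 * rate)) / rate
    kernel = np.exp(-kernel_t / 0.001)
    voice = np.convolve(pulses, kernel)[:n]
    if seed is not None:
        voice = voice + np.random.default_rng(seed).normal(0.0, 0.01, n)
    amp = amplitude if np.isscalar(amplitude) else np.interp(
        t, amplitude[0], amplitude[1]
    )
    voice = voice / max(np.abs(voice).max(), 1e-9) * amp
    return voice


# ---------------------------------------------------------------------------
# study-level helpers
# ---------------------------------------------------------------------------


def simulate_acoustic_study(cfg: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-grade x modality acoustic means for a whole study.

    Runs the real pipeline path: generated series -> modality labelling ->
    per-grade aggregation.  Trajectory synthesis is skipped (the acoustic
    series do not need it beyond hand-speed coupling, which is irrelevant
    to the per-grade means).
    """
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg = replace(cfg, emit_trajectories=False)
    tables = []
    for d in range(cfg.n_dyads):
        for m in (0, 1):
            s = generate_session(cfg, d, m)
            s.acoustics.modality = iof.assign_modality(
                s.acoustics.times,
                s.voiced_intervals,
                s.events,
                s.participant_id,
                max_drift_s=1.0 / cfg.fps,
            )
            tables.append(
                ac.acoustics_by_grade(
                    s.acoustics, cfg.schedule, s.participant_id, s.dyad_id
                )
            )
    return pd.concat(tables, ignore_index=True)


def simulate_feature_table(
    cfg: GeneratorConfig,
    seed: int | None = None,
    events_per_participant_grade: float | None = None,
) -> pd.DataFrame:
    """Per-gesture kinematic feature table drawn from the generative model.

    This samples features directly from the model that the trajectory
    synthesis realises (log-normal noise around grade-modulated base
    values, Poisson submovement counts), which is what the statistics
    ladder assumes; it is the fast route for calibration and power
    studies at full study scale.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    features = ["size", "peak_velocity", "hold_time", "depth"]
    bases = {
        "size": cfg.base_size_px2,
        "peak_velocity": MINJERK_PEAK_FACTOR * cfg.base_pulse_amp_px / cfg.base_pulse_dur_s,
        "hold_time": cfg.base_hold_s,
        "depth": cfg.base_depth_px,
    }
    gtypes = list(GESTURE_TYPE_PROBS)
    probs = np.array([GESTURE_TYPE_PROBS[g] for g in gtypes])
    probs = probs / probs.sum()
    gt_effects = {
        g: {f: float(np.exp(rng.normal(0.0, cfg.gesture_type_sd))) for f in features}
        for g in gtypes
    }
    rows = []
    minutes = cfg.grade_duration_s / 60.0
    for d in range(cfg.n_dyads):
        d_eff = {f: float(np.exp(rng.normal(0.0, cfg.dyad_sd))) for f in features}
        for m in (0, 1):
            p_eff = {
                f: float(np.exp(rng.normal(0.0, cfg.participant_sd))) for f in features
            }
            pid = f"d{d:02d}p{m}"
            for grade in range(1, cfg.n_grades + 1):
                if events_per_participant_grade is None:
                    n_ev = rng.poisson(float(cfg.gesture_rate_fn(grade)) * minutes)
                else:
                    n_ev = rng.poisson(events_per_participant_grade)
                for _ in range(n_ev):
                    gtype = str(rng.choice(gtypes, p=probs))
                    row = {
                        "participant": pid,
                        "dyad": f"d{d:02d}",
                        "grade": grade,
                        "gesture_type": gtype,
                    }
                    for f in features:
                        mu = (
                            bases[f]
                            * float(cfg.effect_multiplier(f, grade))
                            * d_eff[f]
                            * p_eff[f]
                            * gt_effects[gtype][f]
                        )
                        row[f] = mu * float(np.exp(rng.normal(0.0, cfg.noise_sd[f])))
                    lam = cfg.mean_submovements * float(
                        cfg.effect_multiplier("submovements", grade)
                    )
                    row["submovements"] = 1 + int(rng.poisson(max(lam - 1, 0.05)))
                    rows.append(row)
    return pd.DataFrame(rows)


def generate_study(cfg: GeneratorConfig, out_dir) -> pd.DataFrame:
    """Write a full synthetic study as the input-format file tree.

    Creates ``<out>/d00p0/{front.json, side.json, gestures.tsv,
    acoustics.csv}`` per participant plus a study-level ``schedule.yaml``
    and ``truth.csv``; returns the concatenated truth table.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = []
    for d in range(cfg.n_dyads):
        for m in (0, 1):
            s = generate_session(cfg, d, m)
            pdir = out / s.participant_id
            pdir.mkdir(exist_ok=True)
            if s.front is not None:
                iof.write_keypoints(s.front, pdir / "front.json")
                iof.write_keypoints(s.side, pdir / "side.json")
            iof.write_annotations(s.events, pdir / "gestures.tsv")
            pd.DataFrame(
                {
                    "time_s": s.acoustics.times,
                    "envelope": s.acoustics.envelope,
                    "intensity_db": s.acoustics.intensity_db,
                    "f0_hz": s.acoustics.f0_hz,
                }
            ).to_csv(pdir / "acoustics.csv", index=False)
            pd.DataFrame(s.voiced_intervals, columns=["start", "end"]).to_csv(
                pdir / "voiced.csv", index=False
            )
            truths.append(s.truth)
    with open(out / "schedule.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "fps": cfg.fps,
                "n_grades": cfg.n_grades,
                "grade_duration_s": cfg.grade_duration_s,
                "direction": cfg.direction,
                "confidence_floor": iof.DEFAULT_CONFIDENCE_FLOOR,
            },
            fh,
        )
    truth = pd.concat(truths, ignore_index=True)
    truth.to_csv(out / "truth.csv", index=False)
    return truth
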