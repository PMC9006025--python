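"""Gesture kinematic features: closed forms, detection and invariances."""

import numpy as np
import pandas as pd
import pytest

from gespeech import kinematics as kin
from gespeech.io_formats import BlurSchedule, GestureEvent
from gespeech.synthetic_data import minimum_jerk_displacement

from conftest import make_trajectory


def hands_fn(xy_series):
    """positions_fn moving both hands along the same series."""
    def fn(k, t):
        if k in (4, 7):
            return xy_series
        return None
    return fn


def pulse_profile(fps, segments):
    """Concatenate (amplitude, duration) min-jerk pulses and (None, gap)s
    into a hand displacement series; returns (positions, truth_gaps)."""
    parts = [np.zeros(int(0.3 * fps))]
    pos = 0.0
    direction = 1.0
    for amp, dur in segments:
        n = int(round(dur * fps))
        if amp is None:
            parts.append(np.full(n, pos))
        else:
            prof = pos + direction * amp * minimum_jerk_displacement(n)
            pos = prof[-1]
            parts.append(prof)
            direction = -direction
    parts.append(np.full(int(0.3 * fps), pos))
    d = np.concatenate(parts)
    return np.column_stack([450 + d, 430 * np.ones(d.size)])


class TestVelocity:
    def test_static_hands_zero_profile(self, static_traj):
        ev = GestureEvent(0.2, 3.0, "pragmatic", "p", "d")
        prof = kin.velocity_profile(static_traj, ev)
        assert np.allclose(prof["mean"], 0.0)

    def test_uniform_motion_closed_form(self):
        xy = np.column_stack([400 + 2.0 * np.arange(100), np.full(100, 430.0)])
        traj = make_trajectory(hands_fn(xy), n_frames=100, fps=25.0)
        ev = GestureEvent(0.4, 3.2, "pragmatic", "p", "d")
        prof = kin.velocity_profile(traj, ev, smooth_cutoff_hz=0)["mean"]
        assert np.allclose(prof, 50.0)  # 2 px/frame * 25 fps

    def test_sinusoid_peak_speed_analytic(self):
        """x(t) = A sin(2 pi f t) at 100 fps -> peak speed ~ 2 pi f A."""
        fps, A, f = 100.0, 50.0, 1.5
        t = np.arange(600) / fps
        xy = np.column_stack([500 + A * np.sin(2 * np.pi * f * t), np.full(t.size, 430.0)])
        traj = make_trajectory(hands_fn(xy), n_frames=600, fps=fps)
        ev = GestureEvent(0.5, 5.5, "pragmatic", "p", "d")
        peak = kin.peak_velocity(kin.velocity_profile(traj, ev)["mean"])
        assert peak == pytest.approx(2 * np.pi * f * A, rel=0.02)

    def test_event_outside_trajectory_rejected(self, static_traj):
        ev = GestureEvent(3.0, 9.0, "pragmatic", "p", "d")
        with pytest.raises(ValueError):
            kin.velocity_profile(static_traj, ev)

    def test_peak_velocity_is_max(self, rng):
        profile = rng.gamma(2.0, 30.0, 500)
        assert kin.peak_velocity(profile) == profile.max()
        assert kin.peak_velocity([0, 10, 80, 10]) == 80
        assert kin.peak_velocity(np.full(7, 50.0)) == 50.0


class TestSubmovements:
    fps = 50.0

    def _detect(self, segments):
        xy = pulse_profile(self.fps, segments)
        speed = np.hypot(*np.diff(xy, axis=0).T) * self.fps
        return kin.detect_submovements(speed, self.fps)

    def test_single_pulse(self):
        assert self._detect([(80, 0.5)]).count == 1

    def test_three_separated_pulses(self):
        sub = self._detect(
            [(80, 0.5), (None, 0.5), (60, 0.4), (None, 0.6), (90, 0.5)]
        )
        assert sub.count == 3
        assert sub.boundaries.size == 2

    def test_fused_pulses_merge_to_one(self):
        """Overlapping pulses whose valley stays above the valley fraction."""
        n = int(0.5 * self.fps)
        prof = minimum_jerk_displacement(n)
        v1 = np.concatenate([np.diff(prof), np.zeros(n // 2)])
        v2 = np.concatenate([np.zeros(n // 2), np.diff(prof)])
        v = (v1 + v2) * 80 * self.fps  # valley ~70% of peaks
        assert kin.detect_submovements(v, self.fps).count == 1

    def test_all_zero_profile(self):
        assert kin.detect_submovements(np.zeros(100), self.fps).count == 0


class TestHoldTime:
    fps = 50.0

    def _hold(self, segments):
        xy = pulse_profile(self.fps, segments)
        speed = np.hypot(*np.diff(xy, axis=0).T) * self.fps
        return kin.hold_time(speed, self.fps)

    def test_continuous_motion_no_hold(self):
        assert self._hold([(80, 0.6), (70, 0.6)]) == pytest.approx(0.0, abs=0.05)

    def test_half_second_gap_recovered(self):
        """A 0.5 s inter-pulse gap is recovered within one frame per
        boundary of the dense-sampling oracle (the same stillness rule
        applied to a 20x oversampled profile; sub-threshold pulse tails
        are part of thresholded stillness by definition)."""
        segments = [(80, 0.2), (None, 0.5), (80, 0.2)]
        h = self._hold(segments)
        hi_fps = 1000.0
        xy = pulse_profile(hi_fps, segments)
        speed = np.hypot(*np.diff(xy, axis=0).T) * hi_fps
        oracle = kin.hold_time(speed, hi_fps)
        assert oracle == pytest.approx(0.5, abs=0.1)  # gap dominates
        assert h == pytest.approx(oracle, abs=2.0 / self.fps)

    def test_pre_gesture_rest_excluded(self):
        """Stillness before onset (and after offset) never counts."""
        h = self._hold([(None, 1.5), (80, 0.5), (None, 1.2)])
        assert h == pytest.approx(0.0, abs=0.05)


class TestSpatial:
    def test_static_hands_zero_size(self, static_traj):
        ev = GestureEvent(0.2, 3.0, "pragmatic", "p", "d")
        assert kin.gesture_size(static_traj, ev)["size"] == pytest.approx(0.0)

    def test_rectangle_closed_form(self):
        """Hand tracing a 100 x 50 px rectangle -> 5000 px^2."""
        t = np.linspace(0, 1, 200)
        x = 420 + 100 * np.clip(np.sin(2 * np.pi * t), 0, 1)
        y = 430 + 50 * np.clip(np.cos(2 * np.pi * t), 0, 1)
        xy = np.column_stack([x, y])
        traj = make_trajectory(hands_fn(xy), n_frames=200)
        ev = GestureEvent(0.0, 199 / 25.0, "pragmatic", "p", "d")
        assert kin.gesture_size(traj, ev)["size"] == pytest.approx(5000.0, rel=1e-3)

    def test_size_matches_bounding_box_oracle(self, rng):
        cloud = rng.normal(0, 30, (150, 2))
        xy = np.array([480.0, 400.0]) + cloud
        traj = make_trajectory(hands_fn(xy), n_frames=150)
        ev = GestureEvent(0.0, 149 / 25.0, "pragmatic", "p", "d")
        got = kin.gesture_size(traj, ev)
        rel = np.vstack([xy - traj.xy(1)[:150]])
        assert got["x_extent"] == pytest.approx(np.ptp(rel[:, 0]))
        assert got["y_extent"] == pytest.approx(np.ptp(rel[:, 1]))

    def test_space_categories(self):
        ev = GestureEvent(0.0, 1.0, "pragmatic", "p", "d")
        # hands at the sternum throughout
        sternum = np.array([500.0, 295.0])
        traj = make_trajectory(hands_fn(np.tile(sternum, (30, 1))), n_frames=30)
        assert kin.mcneillian_space(traj, ev) == "centre-centre"
        # a hand raised above head height
        high = np.tile([500.0, 40.0], (30, 1))
        traj2 = make_trajectory(hands_fn(high), n_frames=30)
        assert kin.mcneillian_space(traj2, ev) == "extra-periphery"

    def test_boundary_assigned_outward(self):
        """A hand exactly on the centre-centre box edge falls in centre."""
        ev = GestureEvent(0.0, 1.0, "pragmatic", "p", "d")
        # shoulder width 140 -> half-box 35 px; sternum at (500, 295)
        edge = np.tile([500.0 + 35.0, 295.0], (30, 1))
        traj = make_trajectory(hands_fn(edge), n_frames=30)
        assert kin.mcneillian_space(traj, ev) == "centre"

    def test_depth(self):
        ev = GestureEvent(0.0, 1.0, "pragmatic", "p", "d")
        n = 30
        def side_fn(reach):
            def fn(k, t):
                if k in (4, 7):
                    return np.column_stack([300 + reach(t), np.full(t.size, 430.0)])
                if k == 8:
                    return np.tile([300.0, 520.0], (t.size, 1))
                return None
            return fn
        at_hip = make_trajectory(side_fn(lambda t: 0 * t), n, view="side",
                                 keypoint_ids=[4, 7, 8])
        assert kin.gesture_depth(at_hip, ev) == pytest.approx(0.0, abs=1e-9)
        reach = make_trajectory(side_fn(lambda t: 120 * np.sin(np.pi * t / t[-1])),
                                n, view="side", keypoint_ids=[4, 7, 8])
        assert kin.gesture_depth(reach, ev) == pytest.approx(120.0, rel=0.01)
        assert np.isnan(kin.gesture_depth(None, ev))

    def test_depth_composes_lean_and_reach(self):
        """30 px of torso lean + 60 px reach -> ~90 px peak depth."""
        ev = GestureEvent(0.0, 1.0, "pragmatic", "p", "d")
        n = 30
        def fn(k, t):
            ramp = np.sin(np.pi * t / t[-1])
            if k in (4, 7):
                return np.column_stack([300 + 90 * ramp, np.full(t.size, 430.0)])
            if k == 8:
                return np.tile([300.0, 520.0], (t.size, 1))
            return None
        traj = make_trajectory(fn, n, view="side", keypoint_ids=[4, 7, 8])
        assert kin.gesture_depth(traj, ev) == pytest.approx(90.0, rel=0.01)


class TestNpvi:
    def test_equal_durations_zero(self):
        assert kin.npvi([0.2, 0.2, 0.2, 0.2]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # |100-200| / 150 * 100 = 66.67
        assert kin.npvi([0.1, 0.2]) == pytest.approx(200.0 / 3.0)

    def test_order_sensitivity(self):
        assert kin.npvi([100, 200, 100]) != kin.npvi([200, 100, 100])

    def test_single_duration_undefined(self):
        assert np.isnan(kin.npvi([0.3]))


class TestRateAndVif:
    def test_rate_closed_form(self):
        sched = BlurSchedule()
        events = [
            GestureEvent(10.0 + i, 10.5 + i, "pragmatic", "p1", "d1", blur_grade=1)
            for i in range(0, 16, 2)
        ]
        table = kin.gesture_rate(events, sched)
        assert table[table.grade == 1].rate_per_min.iloc[0] == pytest.approx(2.0)
        assert table[table.grade == 5].rate_per_min.iloc[0] == 0.0

    def test_rate_poisson_monte_carlo(self, rng):
        """Poisson(3/min) simulated sessions: mean recovered rate ~ 3."""
        sched = BlurSchedule(grade_duration_s=60.0, n_grades=10)
        rates = []
        for _ in range(50):
            events = []
            for g in range(10):
                for _ in range(rng.poisson(3.0)):
                    s = g * 60 + rng.uniform(0, 59)
                    events.append(
                        GestureEvent(s, s + 0.5, "deictic", "p", "d",
                                     blur_grade=g + 1)
                    )
            if events:
                rates.append(kin.gesture_rate(events, sched).rate_per_min.mean())
        assert np.mean(rates) == pytest.approx(3.0, abs=0.15)

    def test_vif_independent_near_one(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (400, 4)), columns=list("abcd"))
        out = kin.vif_screen(df)
        assert (out.vif < 1.2).all()
        assert not out.flagged.any()

    def test_vif_duplicate_flagged_infinite(self, rng):
        df = pd.DataFrame({"a": rng.normal(0, 1, 100)})
        df["b"] = df["a"]
        df["c"] = rng.normal(0, 1, 100)
        out = kin.vif_screen(df)
        assert out[out.feature == "a"].flagged.item()
        assert np.isinf(out[out.feature == "a"].vif.item())

    def test_vif_near_collinear_flagged(self, rng):
        a, b = rng.normal(0, 1, 300), rng.normal(0, 1, 300)
        df = pd.DataFrame({"a": a, "b": b, "c": a + b + rng.normal(0, 0.01, 300)})
        out = kin.vif_screen(df)
        assert out[out.feature == "c"].vif.item() > 3


class TestScaleEquivariance:
    def test_features_scale_as_expected(self, rng):
        """Scaling pixels by c scales velocity/depth by c, size by c^2,
        leaves counts, nPVI and the space category invariant."""
        fps = 50.0
        xy = pulse_profile(fps, [(70, 0.5), (None, 0.5), (50, 0.4)])
        n = xy.shape[0]
        c = 2.5
        ev = GestureEvent(0.0, (n - 1) / fps, "pragmatic", "p", "d")
        base = make_trajectory(hands_fn(xy), n_frames=n, fps=fps)
        scaled = make_trajectory(hands_fn(xy * c), n_frames=n, fps=fps)
        scaled.positions = base.positions * c
        p1 = kin.profile_event(base, ev)
        p2 = kin.profile_event(scaled, ev)
        assert p2.peak_velocity == pytest.approx(c * p1.peak_velocity, rel=1e-6)
        assert p2.size == pytest.approx(c**2 * p1.size, rel=1e-6)
        assert p2.submovements == p1.submovements
        assert p2.npvi == pytest.approx(p1.npvi)
        assert p2.mcneillian_space == p1.mcneillian_space
        assert p2.hold_time == pytest.approx(p1.hold_time)

    def test_hold_plus_movement_bounded_by_duration(self, rng):
        fps = 50.0
        xy = pulse_profile(fps, [(60, 0.4), (None, 0.8), (70, 0.5)])
        n = xy.shape[0]
        ev = GestureEvent(0.0, (n - 1) / fps, "pragmatic", "p", "d")
        traj = make_trajectory(hands_fn(xy), n_frames=n, fps=fps)
        prof = kin.profile_event(traj, ev)
        assert prof.hold_time <= ev.duration_s + 1e-9
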