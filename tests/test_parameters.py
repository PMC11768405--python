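"""Per-cycle gait parameters and aggregation."""

import math

import numpy as np
import pytest

from gaitkit.events import IC, FC, GaitEvent
from gaitkit.parameters import (
    StrideRecord,
    build_strides,
    point_line_distance,
    strides_to_frame,
    summarize,
)
from gaitkit.simulate import GaitSimConfig, simulate
from gaitkit.skeleton import DEFAULT_SKELETON
from gaitkit.trajectories import AnalysisWindow, Trajectory


def _flat_traj(duration: float = 2.0, rate: float = 30.0,
               overrides: dict | None = None) -> Trajectory:
    """All keypoints static; selected keypoints overridden per frame."""
    t = np.arange(0.0, duration, 1.0 / rate)
    k = len(DEFAULT_SKELETON.keypoint_names)
    pos = np.zeros((t.size, k, 3))
    for name, xyz in (overrides or {}).items():
        pos[:, DEFAULT_SKELETON.index(name), :] = xyz
    return Trajectory(t, pos, np.ones((t.size, k), dtype=bool), rate)


def _ev(kind, side, time, x, y=0.0, z=0.0):
    return GaitEvent(kind, side, time, np.array([x, y, z], dtype=float))


def _one_cycle_events():
    """One left gait cycle with a clean contralateral step inside it."""
    return [
        _ev(IC, "left", 0.0, 0.0),
        _ev(FC, "right", 0.15, 0.5, 0.18),
        _ev(IC, "right", 0.55, 0.7, 0.18),
        _ev(FC, "left", 0.7, 0.25),
        _ev(IC, "left", 1.1, 1.4),
    ]


class TestTemporalArithmetic:
    def test_stride_swing_double_support(self):
        recs = build_strides(_one_cycle_events(), _flat_traj())
        (rec,) = recs
        assert rec.stride_time == pytest.approx(1.1)
        assert rec.swing_time == pytest.approx(0.4)
        # loading response 0.15 s + pre-swing 0.15 s
        assert rec.double_support_time == pytest.approx(0.30)

    def test_missing_contralateral_leaves_ds_nan(self):
        events = [e for e in _one_cycle_events() if e.side == "left"]
        (rec,) = build_strides(events, _flat_traj())
        assert math.isnan(rec.double_support_time)
        assert rec.stride_time == pytest.approx(1.1)

    def test_stride_crossing_window_boundary_dropped(self):
        recs = build_strides(_one_cycle_events(), _flat_traj(),
                             windows=[AnalysisWindow(0.0, 1.05)])
        assert recs == []

    def test_ds_fraction_closed_form_on_exact_schedule(self):
        """Symmetric walker, 60 % stance: DS time = 0.2 x stride time."""
        traj, gt = simulate(GaitSimConfig(n_strides=20, seed=9))
        recs = build_strides(gt.events, traj)
        df = strides_to_frame(recs).dropna(subset=["double_support_time"])
        frac = df["double_support_time"] / df["stride_time"]
        assert abs(frac.mean() - 0.2) < (1 / 30.0) / 1.1


class TestSpatial:
    def test_stride_length_and_velocity(self):
        (rec,) = build_strides(_one_cycle_events(), _flat_traj())
        assert rec.stride_length == pytest.approx(1.4)
        assert rec.velocity == pytest.approx(1.4 / 1.1)
        assert rec.velocity * rec.stride_time == pytest.approx(
            rec.stride_length, abs=1e-12)

    def test_stride_width_is_lateral_offset(self):
        (rec,) = build_strides(_one_cycle_events(), _flat_traj())
        assert rec.stride_width == pytest.approx(0.18)

    def test_point_on_line_gives_zero_width(self):
        events = _one_cycle_events()
        events[2] = _ev(IC, "right", 0.55, 0.7, 0.0)  # on the x-axis
        (rec,) = build_strides(events, _flat_traj())
        assert rec.stride_width == pytest.approx(0.0, abs=1e-12)

    def test_point_line_distance_matches_cross_product_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p, a, b = rng.normal(size=(3, 2))
            d = b - a
            oracle = abs(d[0] * (p - a)[1]
                         - d[1] * (p - a)[0]) / np.linalg.norm(d)
            assert point_line_distance(p, a, b) == pytest.approx(oracle,
                                                                 abs=1e-12)

    def test_spatial_params_invariant_to_ground_plane_rotation(self):
        plain, gt_a = simulate(GaitSimConfig(n_strides=10, seed=13))
        turned, gt_b = simulate(GaitSimConfig(n_strides=10, seed=13,
                                              heading_deg=63.0))
        a = strides_to_frame(build_strides(gt_a.events, plain))
        b = strides_to_frame(build_strides(gt_b.events, turned))
        for col in ("stride_length", "stride_width", "fpa_deg"):
            assert np.allclose(a[col], b[col], atol=1e-9)


class TestAngles:
    def _fpa_traj(self, angle_deg: float) -> tuple[list, Trajectory]:
        axis = np.array([math.cos(math.radians(angle_deg)),
                         math.sin(math.radians(angle_deg)), 0.0]) * 0.25
        traj = _flat_traj(overrides={
            "left_heel": np.zeros(3), "left_big_toe": axis,
        })
        return _one_cycle_events(), traj

    @pytest.mark.parametrize("angle", [0.0, 7.5, 30.0])
    def test_fpa_recovers_prescribed_angle(self, angle):
        events, traj = self._fpa_traj(angle)
        (rec,) = build_strides(events, traj)
        assert rec.fpa_deg == pytest.approx(angle, abs=1e-9)

    def test_arm_swing_pendulum_rom(self):
        rate = 120.0
        t = np.arange(0.0, 1.1, 1.0 / rate)
        theta = np.radians(15.0) * np.sin(2 * np.pi * t / 1.1)
        wrist = np.column_stack([
            0.6 * np.sin(theta), np.zeros_like(t), 1.45 - 0.6 * np.cos(theta)
        ])
        traj = _flat_traj(duration=1.1, rate=rate, overrides={
            "left_shoulder": np.array([0.0, 0.0, 1.45]),
            "left_wrist": wrist,
        })
        (rec,) = build_strides(_one_cycle_events(), traj)
        assert rec.arm_swing_rom_deg == pytest.approx(30.0, abs=0.1)

    def test_vertical_arm_has_zero_rom(self):
        traj = _flat_traj(overrides={
            "left_shoulder": np.array([0.0, 0.0, 1.45]),
            "left_wrist": np.array([0.0, 0.0, 0.85]),
        })
        (rec,) = build_strides(_one_cycle_events(), traj)
        assert rec.arm_swing_rom_deg == pytest.approx(0.0, abs=1e-9)

    def test_mediolateral_swing_projects_to_zero(self):
        rate = 60.0
        t = np.arange(0.0, 1.1, 1.0 / rate)
        theta = np.radians(15.0) * np.sin(2 * np.pi * t / 1.1)
        wrist = np.column_stack([
            np.zeros_like(t), 0.6 * np.sin(theta), 1.45 - 0.6 * np.cos(theta)
        ])
        traj = _flat_traj(duration=1.1, rate=rate, overrides={
            "left_shoulder": np.array([0.0, 0.0, 1.45]),
            "left_wrist": wrist,
        })
        (rec,) = build_strides(_one_cycle_events(), traj)
        # walking direction is +x; purely mediolateral motion vanishes
        assert rec.arm_swing_rom_deg == pytest.approx(0.0, abs=1e-6)

    def test_straight_leg_zero_knee_rom(self):
        traj = _flat_traj(overrides={
            "left_hip": np.array([0.0, 0.1, 0.95]),
            "left_knee": np.array([0.0, 0.1, 0.50]),
            "left_ankle": np.array([0.0, 0.1, 0.05]),
        })
        (rec,) = build_strides(_one_cycle_events(), traj)
        assert rec.knee_rom_deg == pytest.approx(0.0, abs=1e-6)

    def test_knee_rom_equals_profile_range(self):
        rate = 120.0
        t = np.arange(0.0, 1.1, 1.0 / rate)
        flex = np.radians(5.0 + 20.0 * (1 - np.cos(2 * np.pi * t / 1.1)))
        hip = np.tile([0.0, 0.1, 0.95], (t.size, 1))
        knee = hip + 0.45 * np.column_stack(
            [np.zeros_like(t), np.zeros_like(t), -np.ones_like(t)])
        ankle = knee + 0.45 * np.column_stack(
            [np.sin(-flex), np.zeros_like(t), -np.cos(-flex)])
        traj = _flat_traj(duration=1.1, rate=rate, overrides={
            "left_hip": hip, "left_knee": knee, "left_ankle": ankle,
        })
        (rec,) = build_strides(_one_cycle_events(), traj)
        assert rec.knee_rom_deg == pytest.approx(40.0, abs=0.1)


class TestSummarize:
    def _records(self, left_vals, right_vals, param="stride_length"):
        recs = []
        for i, v in enumerate(left_vals):
            recs.append(StrideRecord("left", i * 1.0, i * 1.0 + 1,
                                     **{param: v}))
        for i, v in enumerate(right_vals):
            recs.append(StrideRecord("right", i * 1.0 + 0.5, i * 1.0 + 1.5,
                                     **{param: v}))
        return recs

    def test_cv_sample_std_oracle(self):
        recs = self._records([1.0, 1.1], [0.9])
        s = summarize(recs, min_strides_per_side=1)
        assert s["stride_length"]["cv_pct"] == pytest.approx(10.0)

    def test_equal_sides_zero_asymmetry(self):
        recs = self._records([1.0] * 3, [1.0] * 3)
        s = summarize(recs)
        assert s["stride_length"]["asymmetry_pct"] == pytest.approx(0.0)

    def test_asymmetry_formula(self):
        recs = self._records([0.9] * 3, [1.0] * 3)
        s = summarize(recs)
        assert s["stride_length"]["asymmetry_pct"] == pytest.approx(10.0)

    def test_asymmetry_symmetric_under_side_relabeling(self):
        a = summarize(self._records([0.8] * 4, [1.0] * 4))
        b = summarize(self._records([1.0] * 4, [0.8] * 4))
        assert (a["stride_length"]["asymmetry_pct"]
                == pytest.approx(b["stride_length"]["asymmetry_pct"]))
        assert 0 <= a["stride_length"]["asymmetry_pct"] < 100

    def test_too_few_strides_per_side_gives_nan_asymmetry(self):
        recs = self._records([1.0, 1.1], [0.9])
        s = summarize(recs)
        assert math.isnan(s["stride_length"]["asymmetry_pct"])

    def test_velocity_consistency_on_pipeline_output(self, noiseless_bout):
        df = strides_to_frame(noiseless_bout["strides"])
        assert np.allclose(df["velocity"] * df["stride_time"],
                           df["stride_length"], atol=1e-9)

    def test_symmetric_noiseless_bout_is_nearly_symmetric(self, noiseless_bout):
        table = noiseless_bout["summary"].table
        for p in ("stride_time", "stride_length", "velocity"):
            assert table.loc[p, "asymmetry_pct"] < 0.5
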