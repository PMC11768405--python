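"""Kinematic walking simulator with exact ground-truth contacts.

Generates 17-keypoint 3D trajectories of straight-path walking at a
commanded speed, cadence and stride length, with configurable
stride-to-stride variability, left-right asymmetry, sensor noise and
short dropouts. The model is kinematic, not dynamic: every downstream
computation consumes positions only, so sinusoid/spline joint profiles
suffice.

Contact schedule: alternating step durations are drawn around half the
commanded stride time (Gaussian, truncated at +/-3 sigma), giving each
foot a stance phase of ``stance_fraction`` of its stride and a swing
phase that translates the foot forward by its drawn stride length with
a half-sine velocity profile (zero speed at lift-off and touchdown,
peak mid-swing well above the walking speed, so the default adaptive
thresholds are discriminative). Ground-truth IC/FC times come from the
schedule itself, never re-derived from the trajectory.

Body model: pelvis/shoulders/head advance at the mean walking speed;
thigh-shank chains realize a two-peak knee-flexion profile whose
max - min equals the commanded knee ROM; arms swing as anti-phase
pendulums in the sagittal plane with ROM equal to the commanded arm
swing; feet realize the commanded foot progression angle and step
width. All randomness flows from a single seeded generator.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .events import FC, IC, GaitEvent
from .parameters import ParameterSummary, StrideRecord, summarize
from .skeleton import DEFAULT_SKELETON
from .trajectories import Trajectory

_FOOT_LENGTH = 0.25     # heel -> big toe, m
_SWING_CLEARANCE = 0.05  # peak heel lift during swing, m
_THIGH = 0.45
_SHANK = 0.45
_ARM = 0.60
_HIP_HALF_WIDTH = 0.11
_SHOULDER_HALF_WIDTH = 0.18
_HIP_HEIGHT = 0.95
_SHOULDER_HEIGHT = 1.45
_HEAD_HEIGHT = 1.68
_THIGH_SWING_DEG = 20.0


@dataclass
class GaitSimConfig:
    """Commanded walking conditions.

    Defaults describe typical healthy adult gait: 1.2 m/s, 1.1 s stride
    time (hence 1.32 m strides), 60% stance, ~0.18 m step width, 7 deg
    out-toeing, 30 deg arm-swing ROM and 40 deg knee ROM, sampled at
    30 Hz. ``speed = stride_length / stride_time`` is enforced.
    Asymmetries are percent differences applied as per-side scaling
    (the left side keeps the nominal value).
    """

    speed: float = 1.2
    stride_time: float = 1.1
    stride_length: float | None = None
    stance_fraction: float = 0.6
    n_strides: int = 30
    stride_time_cv: float = 3.0
    stride_length_cv: float = 3.0
    stride_length_asymmetry_pct: float = 0.0
    arm_swing_rom_deg: float = 30.0
    arm_swing_asymmetry_pct: float = 0.0
    knee_rom_deg: float = 40.0
    knee_rom_asymmetry_pct: float = 0.0
    fpa_deg: float = 7.0
    step_width: float = 0.18
    noise_std: float = 0.0
    dropout_per_min: float = 0.0
    rate: float = 30.0
    lead_in: float = 0.5
    lead_out: float = 0.5
    heading_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_length is None:
            self.stride_length = self.speed * self.stride_time
        if not math.isclose(self.speed, self.stride_length / self.stride_time,
                            rel_tol=1e-2):
            raise ValueError(
                "inconsistent config: speed must equal "
                "stride_length / stride_time"
            )
        if not 0.5 < self.stance_fraction < 0.8:
            raise ValueError("stance_fraction must be in (0.5, 0.8)")
        if min(self.stride_time_cv, self.stride_length_cv) < 0:
            raise ValueError("CVs must be non-negative")
        if self.n_strides < 2:
            raise ValueError("need at least 2 strides per side")


@dataclass
class GroundTruth:
    """Exact contact events and commanded per-stride parameter values."""

    events: list[GaitEvent]
    stride_table: list[StrideRecord]
    summary: ParameterSummary = field(repr=False, default=None)  # type: ignore[assignment]


def _truncated_normal(rng, mean, sd, size):
    if np.isscalar(sd) and sd == 0:
        return np.full(size, mean, dtype=float)
    x = rng.normal(0.0, 1.0, size)
    x = np.clip(x, -3.0, 3.0)
    return mean + sd * x


def _knee_shape(phi: np.ndarray, stance: float) -> np.ndarray:
    """Two-peak normalized flexion profile: small stance wave (0.25 of
    the range) and a swing peak reaching 1; minima at 0 exactly."""
    phi = np.mod(phi, 1.0)
    out = np.empty_like(phi)
    st = phi < stance
    out[st] = 0.25 * np.sin(np.pi * phi[st] / stance) ** 2
    out[~st] = np.sin(np.pi * (phi[~st] - stance) / (1.0 - stance)) ** 2
    return out


class _FootSchedule:
    """One foot's contact schedule and piecewise kinematics."""

    def __init__(self, ic_times, fc_times, x_positions, y, fpa_rad):
        self.ic = np.asarray(ic_times)        # t_0 .. t_{m}
        self.fc = np.asarray(fc_times)        # toe-offs of strides 0..m-1
        self.x = np.asarray(x_positions)      # heel x at each IC
        self.y = y
        self.fpa = fpa_rad

    def heel_toe(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = t.size
        x = np.empty(n)
        z = np.zeros(n)
        j = np.searchsorted(self.fc, t, side="right") - 1
        standing = j < 0
        x[standing] = self.x[0]
        moving = ~standing
        jm = j[moving]
        t_land = self.ic[jm + 1]
        in_swing = moving.copy()
        in_swing[moving] = t[moving] < t_land
        in_stance = moving & ~in_swing
        js = j[in_swing]
        tau = (t[in_swing] - self.fc[js]) / (self.ic[js + 1] - self.fc[js])
        x[in_swing] = self.x[js] + (self.x[js + 1] - self.x[js]) * (
            1.0 - np.cos(np.pi * tau)
        ) / 2.0
        z[in_swing] = _SWING_CLEARANCE * np.sin(np.pi * tau) ** 2
        x[in_stance] = self.x[j[in_stance] + 1]
        heel = np.column_stack([x, np.full(n, self.y), z])
        toe = heel + np.array(
            [_FOOT_LENGTH * math.cos(self.fpa),
             _FOOT_LENGTH * math.sin(self.fpa), 0.0]
        )
        return heel, toe

    def phase(self, t: np.ndarray) -> np.ndarray:
        """Gait-cycle phase in [0, 1); 0 while standing before/after."""
        k = np.searchsorted(self.ic, t, side="right") - 1
        phi = np.zeros(t.size)
        ok = (k >= 0) & (k < self.ic.size - 1)
        kk = k[ok]
        phi[ok] = (t[ok] - self.ic[kk]) / (self.ic[kk + 1] - self.ic[kk])
        return phi


def simulate(cfg: GaitSimConfig) -> tuple[Trajectory, GroundTruth]:
    """Generate one walking bout; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    T, f = cfg.stride_time, cfg.stance_fraction
    n = cfg.n_strides

    # --- contact schedule: alternating steps, left leads -------------
    n_ic = n + 2  # ICs t_0..t_{n+1} per side -> n recorded cycles
    n_steps = 2 * n_ic - 1
    sigma_step = (cfg.stride_time_cv / 100.0) * T / math.sqrt(2.0)
    steps = _truncated_normal(rng, T / 2.0, sigma_step, n_steps)
    u = cfg.lead_in + np.concatenate(([0.0], np.cumsum(steps)))
    ic_times = {"left": u[0::2], "right": u[1::2]}  # each length n_ic

    # --- stride lengths with per-side scaling ------------------------
    L0 = cfg.stride_length
    scale = {"left": 1.0,
             "right": 1.0 - cfg.stride_length_asymmetry_pct / 100.0}
    heel_x = {}
    for side, x0 in (("left", 0.0), ("right", L0 / 2.0)):
        mean_l = L0 * scale[side]
        draws = _truncated_normal(
            rng, mean_l, (cfg.stride_length_cv / 100.0) * mean_l, n_ic - 1
        )
        heel_x[side] = x0 + np.concatenate(([0.0], np.cumsum(draws)))

    side_sign = {"left": 1.0, "right": -1.0}
    scheds = {}
    for side in ("left", "right"):
        t_ic = ic_times[side]
        fc = t_ic[:-1] + f * np.diff(t_ic)  # toe-offs of strides 0..n
        scheds[side] = _FootSchedule(
            t_ic, fc, heel_x[side],
            side_sign[side] * cfg.step_width / 2.0,
            math.radians(side_sign[side] * cfg.fpa_deg),
        )

    end_time = max(ic_times["left"][-1], ic_times["right"][-1]) + cfg.lead_out
    dt = 1.0 / cfg.rate
    t = np.arange(0.0, end_time + dt / 2.0, dt)
    nf = t.size

    skeleton = DEFAULT_SKELETON
    k = len(skeleton.keypoint_names)
    pos = np.zeros((nf, k, 3))

    def put(name, arr):
        pos[:, skeleton.index(name), :] = arr

    # --- trunk advances at the mean walking speed --------------------
    walk_start, walk_stop = cfg.lead_in, end_time - cfg.lead_out
    v_mean = L0 * (1.0 + scale["right"]) / 2.0 / T
    xb = v_mean * (np.clip(t, walk_start, walk_stop) - walk_start)
    put("head", np.column_stack([xb, np.zeros(nf),
                                 np.full(nf, _HEAD_HEIGHT)]))

    arm_rom = {
        "left": cfg.arm_swing_rom_deg,
        "right": cfg.arm_swing_rom_deg * (1.0 - cfg.arm_swing_asymmetry_pct / 100.0),
    }
    knee_rom_cmd = {
        "left": cfg.knee_rom_deg,
        "right": cfg.knee_rom_deg * (1.0 - cfg.knee_rom_asymmetry_pct / 100.0),
    }

    for side in ("left", "right"):
        s = side_sign[side]
        sched = scheds[side]
        phi = sched.phase(t)
        heel, toe = sched.heel_toe(t)
        put(f"{side}_heel", heel)
        put(f"{side}_big_toe", toe)

        hip = np.column_stack([xb, np.full(nf, s * _HIP_HALF_WIDTH),
                               np.full(nf, _HIP_HEIGHT)])
        put(f"{side}_hip", hip)
        # thigh swings about vertical; shank adds the flexion angle
        alpha = np.radians(_THIGH_SWING_DEG) * np.cos(2 * np.pi * phi)
        theta = np.radians(knee_rom_cmd[side] * _knee_shape(phi, f))
        knee = hip + _THIGH * np.column_stack(
            [np.sin(alpha), np.zeros(nf), -np.cos(alpha)]
        )
        ankle = knee + _SHANK * np.column_stack(
            [np.sin(alpha - theta), np.zeros(nf), -np.cos(alpha - theta)]
        )
        put(f"{side}_knee", knee)
        put(f"{side}_ankle", ankle)

        shoulder = np.column_stack(
            [xb, np.full(nf, s * _SHOULDER_HALF_WIDTH),
             np.full(nf, _SHOULDER_HEIGHT)]
        )
        put(f"{side}_shoulder", shoulder)
        # anti-phase pendulum; per-cycle ROM = commanded (max - min of a
        # full sinusoid period)
        beta = np.radians(arm_rom[side] / 2.0) * np.sin(2 * np.pi * phi + np.pi)
        arm_dir = np.column_stack([np.sin(beta), np.zeros(nf), -np.cos(beta)])
        put(f"{side}_elbow", shoulder + 0.5 * _ARM * arm_dir)
        put(f"{side}_wrist", shoulder + _ARM * arm_dir)

    # --- ground truth (before noise; events exact by construction) ---
    events: list[GaitEvent] = []
    for side in ("left", "right"):
        sched = scheds[side]
        foot_vec = np.array([_FOOT_LENGTH * math.cos(sched.fpa),
                             _FOOT_LENGTH * math.sin(sched.fpa), 0.0])
        for kdx in range(1, sched.ic.size):
            p = np.array([sched.x[kdx], sched.y, 0.0])
            events.append(GaitEvent(IC, side, float(sched.ic[kdx]), p))
        for kdx in range(sched.fc.size):
            p = np.array([sched.x[kdx], sched.y, 0.0]) + foot_vec
            events.append(GaitEvent(FC, side, float(sched.fc[kdx]), p))
    events.sort(key=lambda e: e.time)

    stride_table: list[StrideRecord] = []
    for side in ("left", "right"):
        sched = scheds[side]
        opp = scheds["right" if side == "left" else "left"]
        for kdx in range(1, sched.ic.size - 1):
            t0, t1 = sched.ic[kdx], sched.ic[kdx + 1]
            rec = StrideRecord(side, float(t0), float(t1))
            rec.stride_time = float(t1 - t0)
            rec.swing_time = float(t1 - sched.fc[kdx])
            o_ic = opp.ic[(opp.ic > t0) & (opp.ic < t1)]
            o_fc = opp.fc[(opp.fc > t0) & (opp.fc < t1)]
            if o_ic.size == 1 and o_fc.size == 1 and o_fc[0] < o_ic[0]:
                rec.double_support_time = float(
                    (o_fc[0] - t0) + (sched.fc[kdx] - o_ic[0])
                )
            rec.stride_length = float(sched.x[kdx + 1] - sched.x[kdx])
            rec.velocity = rec.stride_length / rec.stride_time
            rec.stride_width = cfg.step_width
            rec.fpa_deg = cfg.fpa_deg
            rec.arm_swing_rom_deg = arm_rom[side]
            rec.knee_rom_deg = knee_rom_cmd[side]
            stride_table.append(rec)
    stride_table.sort(key=lambda r: r.cycle_start_time)

    # --- world-frame heading, noise, dropouts ------------------------
    if cfg.heading_deg:
        c, sH = math.cos(math.radians(cfg.heading_deg)), math.sin(
            math.radians(cfg.heading_deg))
        rot = np.array([[c, -sH, 0.0], [sH, c, 0.0], [0.0, 0.0, 1.0]])
        pos = pos @ rot.T
        for ev in events:
            ev.foot_position = rot @ ev.foot_position

    if cfg.noise_std > 0:
        pos = pos + rng.normal(0.0, cfg.noise_std, pos.shape)

    mask = np.ones((nf, k), dtype=bool)
    if cfg.dropout_per_min > 0:
        n_gaps = rng.poisson(cfg.dropout_per_min * end_time / 60.0)
        max_len = max(2, int(0.250 * cfg.rate) - 1)  # gaps stay < 250 ms
        for _ in range(n_gaps):
            kp = int(rng.integers(0, k))
            length = int(rng.integers(2, max_len + 1))
            start = int(rng.integers(1, max(2, nf - length - 1)))
            mask[start:start + length, kp] = False

    traj = Trajectory(t, pos, mask, cfg.rate, skeleton, "z")
    gt = GroundTruth(events, stride_table, summarize(stride_table))
    return traj, gt


def make_reference_pair(
    events: list[GaitEvent],
    jitter_std: float = 0.0,
    miss_rate: float = 0.0,
    extra_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[GaitEvent], list[GaitEvent]]:
    """Perturbed candidate / pristine reference event pair.

    The candidate copy gets Gaussian timing jitter, random deletions
    (``miss_rate``) and random spurious insertions (``extra_rate`` as a
    fraction of the original count), so expected TP/FN/FP counts follow
    the commanded rates. The reference is an unperturbed copy.
    """
    if not (0 <= miss_rate < 1 and 0 <= extra_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    reference = [copy.deepcopy(e) for e in events]
    candidate: list[GaitEvent] = []
    for e in events:
        if rng.random() < miss_rate:
            continue
        c = copy.deepcopy(e)
        if jitter_std > 0:
            c.time += float(rng.normal(0.0, jitter_std))
        candidate.append(c)
    if events:
        n_extra = int(rng.binomial(len(events), extra_rate))
        t_lo = min(e.time for e in events)
        t_hi = max(e.time for e in events)
        for _ in range(n_extra):
            proto = events[int(rng.integers(0, len(events)))]
            candidate.append(GaitEvent(
                proto.kind, proto.side,
                float(rng.uniform(t_lo, t_hi)),
                proto.foot_position.copy(),
            ))
    candidate.sort(key=lambda e: e.time)
    return candidate, reference
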