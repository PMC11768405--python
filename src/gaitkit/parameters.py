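"""Per-gait-cycle parameters and their aggregation.

A gait cycle (stride) runs between two successive initial contacts of
the same foot. Temporal parameters come straight from the event times;
spatial parameters are computed in the ground plane (the vertical
coordinate of a heel strike would otherwise contaminate lengths):

- stride_time   = t_IC(k+1) - t_IC(k)
- swing_time    = t_IC(k+1) - t_FC(k)             (same side)
- double_support_time = sum of the two both-feet-on-ground intervals
  within the cycle, each t_FC(one foot) - t_IC(other foot)
- stride_length = ground-plane distance between successive same-side
  IC heel positions
- stride_width  = perpendicular ground-plane distance of the intervening
  opposite-foot IC position to this stride's line of progression
- velocity      = stride_length / stride_time
- fpa           = unsigned ground-plane angle between the line of
  progression and the stance-average heel->toe foot axis
- arm_swing_rom = max - min sagittal-plane inclination of the
  shoulder->wrist line within the cycle
- knee_rom      = max - min knee flexion (180 deg minus the interior
  hip-knee-ankle angle, so a straight leg is 0 deg flexion)

Aggregation: mean over all cycles (sides pooled), stride-to-stride
variability as CV = 100 * sample std / mean, and side asymmetry as
100 * (1 - smaller-side mean / larger-side mean).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .events import FC, IC, GaitEvent
from .trajectories import AnalysisWindow, Trajectory

log = logging.getLogger(__name__)

PARAMETERS = (
    "stride_time", "swing_time", "double_support_time",
    "stride_length", "stride_width", "velocity",
    "fpa_deg", "arm_swing_rom_deg", "knee_rom_deg",
)


@dataclass
class StrideRecord:
    """Parameter values of one gait cycle; NaN = not computable."""

    side: str
    cycle_start_time: float
    cycle_end_time: float
    stride_time: float = float("nan")
    swing_time: float = float("nan")
    double_support_time: float = float("nan")
    stride_length: float = float("nan")
    stride_width: float = float("nan")
    velocity: float = float("nan")
    fpa_deg: float = float("nan")
    arm_swing_rom_deg: float = float("nan")
    knee_rom_deg: float = float("nan")


@dataclass
class ParameterSummary:
    """Per-parameter mean / CV [%] / side asymmetry [%] table."""

    table: pd.DataFrame
    n_strides_left: int
    n_strides_right: int

    def __getitem__(self, parameter: str) -> pd.Series:
        return self.table.loc[parameter]


def strides_to_frame(strides: list[StrideRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(StrideRecord)]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in strides],
                        columns=cols)


# ---------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------

def _ground(p: np.ndarray, traj: Trajectory) -> np.ndarray:
    """Project point(s) onto the ground plane (drop the up coordinate)."""
    gi = traj.ground_indices
    return np.asarray(p)[..., list(gi)]


def point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Perpendicular distance of 2D point p to the line through a, b."""
    p, a, b = (np.asarray(x, dtype=float) for x in (p, a, b))
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        return float(np.linalg.norm(p - a))
    return float(abs(d[0] * (p[1] - a[1]) - d[1] * (p[0] - a[0])) / n)


def _unsigned_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned acute angle (0-90 deg) between two 2D directions."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    c = abs(float(np.dot(u, v)) / (nu * nv))
    return math.degrees(math.acos(min(1.0, c)))


def _frame_slice(traj: Trajectory, t0: float, t1: float) -> slice:
    i0 = int(np.searchsorted(traj.timestamps, t0, side="left"))
    i1 = int(np.searchsorted(traj.timestamps, t1, side="right"))
    return slice(i0, i1)


# ---------------------------------------------------------------------
# per-cycle operations
# ---------------------------------------------------------------------

def build_strides(
    events: list[GaitEvent],
    traj: Trajectory,
    windows: list[AnalysisWindow] | None = None,
) -> list[StrideRecord]:
    """Temporal skeleton of every stride: one record per same-side
    IC->IC interval (dropped entirely when it crosses a window
    boundary). Double support needs the contralateral IC and FC inside
    the cycle; when they are missing the field is left NaN."""
    records: list[StrideRecord] = []
    by = {
        (k, s): sorted((e for e in events if e.kind == k and e.side == s),
                       key=lambda e: e.time)
        for k in (IC, FC) for s in ("left", "right")
    }
    for side in ("left", "right"):
        opp = "right" if side == "left" else "left"
        ics = by[(IC, side)]
        fcs = by[(FC, side)]
        opp_ics = by[(IC, opp)]
        opp_fcs = by[(FC, opp)]
        for e0, e1 in zip(ics, ics[1:]):
            t0, t1 = e0.time, e1.time
            if windows is not None and not any(
                w.contains(t0) and w.start_time <= t1 <= w.end_time
                for w in windows
            ):
                continue
            rec = StrideRecord(side, t0, t1, stride_time=t1 - t0)
            own_fc = [e for e in fcs if t0 < e.time < t1]
            if len(own_fc) == 1:
                rec.swing_time = t1 - own_fc[0].time
            elif own_fc:
                log.info("%s stride at %.3f s has %d own FCs; swing omitted",
                         side, t0, len(own_fc))
            o_ic = [e for e in opp_ics if t0 < e.time < t1]
            o_fc = [e for e in opp_fcs if t0 < e.time < t1]
            if len(own_fc) == 1 and len(o_ic) == 1 and len(o_fc) == 1 \
                    and o_fc[0].time < o_ic[0].time:
                # loading response: own IC -> opposite toe-off
                ds1 = o_fc[0].time - t0
                # pre-swing: opposite IC -> own toe-off
                ds2 = own_fc[0].time - o_ic[0].time
                rec.double_support_time = ds1 + ds2
            _fill_spatial(rec, e0, e1, o_ic[0] if len(o_ic) == 1 else None, traj)
            if len(own_fc) == 1:
                rec.fpa_deg = foot_progression_angle(rec, e0, e1, own_fc[0], traj)
            rec.arm_swing_rom_deg = arm_swing_rom(rec, e0, e1, traj)
            rec.knee_rom_deg = knee_rom(rec, traj)
            records.append(rec)
    records.sort(key=lambda r: r.cycle_start_time)
    return records


def _fill_spatial(
    rec: StrideRecord,
    e0: GaitEvent,
    e1: GaitEvent,
    opp_ic: GaitEvent | None,
    traj: Trajectory,
) -> None:
    p0 = _ground(e0.foot_position, traj)
    p1 = _ground(e1.foot_position, traj)
    rec.stride_length = float(np.linalg.norm(p1 - p0))
    if rec.stride_time > 0:
        rec.velocity = rec.stride_length / rec.stride_time
    if opp_ic is not None:
        q = _ground(opp_ic.foot_position, traj)
        rec.stride_width = point_line_distance(q, p0, p1)
    else:
        log.info("%s stride at %.3f s: no single opposite IC; width omitted",
                 rec.side, rec.cycle_start_time)


def stride_width(
    rec: StrideRecord, e0: GaitEvent, e1: GaitEvent,
    opp_ic: GaitEvent, traj: Trajectory,
) -> float:
    """Perpendicular ground-plane distance of the opposite-foot IC to
    this stride's line of progression."""
    p0 = _ground(e0.foot_position, traj)
    p1 = _ground(e1.foot_position, traj)
    return point_line_distance(_ground(opp_ic.foot_position, traj), p0, p1)


def foot_progression_angle(
    rec: StrideRecord,
    e0: GaitEvent,
    e1: GaitEvent,
    own_fc: GaitEvent,
    traj: Trajectory,
    min_stance_frames: int = 3,
) -> float:
    """Unsigned angle between the line of progression and the foot axis.

    Foot axis = time-average over the stance phase (IC to same-side FC)
    of the ground-plane heel->toe vector; out-toeing and in-toeing are
    both positive (0-90 deg).
    """
    side = rec.side
    sl = _frame_slice(traj, e0.time, own_fc.time)
    heel = traj.get(traj.skeleton.heel(side))[sl]
    toe = traj.get(traj.skeleton.toe(side))[sl]
    axis3 = toe - heel
    ok = np.isfinite(axis3).all(axis=1)
    if ok.sum() < min_stance_frames:
        log.info("%s stride at %.3f s: stance too short for FPA",
                 side, rec.cycle_start_time)
        return float("nan")
    foot_axis = _ground(axis3[ok].mean(axis=0), traj)
    progression = _ground(e1.foot_position, traj) - _ground(e0.foot_position, traj)
    return _unsigned_angle_deg(progression, foot_axis)


def arm_swing_rom(
    rec: StrideRecord,
    e0: GaitEvent,
    e1: GaitEvent,
    traj: Trajectory,
    max_invalid_fraction: float = 0.2,
) -> float:
    """Sagittal-plane ROM of the shoulder->wrist line over the cycle.

    The shoulder->wrist vector is projected onto the plane spanned by
    the walking direction (ground-plane direction of this cycle's line
    of progression) and the up axis; ROM = max - min inclination.
    Motion perpendicular to the walking direction does not contribute.
    """
    side = rec.side
    sl = _frame_slice(traj, e0.time, e1.time)
    sh = traj.get(f"{side}_shoulder")[sl]
    wr = traj.get(f"{side}_wrist")[sl]
    v = wr - sh
    ok = np.isfinite(v).all(axis=1)
    if ok.size == 0 or (~ok).mean() > max_invalid_fraction or ok.sum() < 3:
        return float("nan")
    w = _ground(e1.foot_position, traj) - _ground(e0.foot_position, traj)
    nw = np.linalg.norm(w)
    if nw == 0:
        return float("nan")
    w = w / nw
    gi = list(traj.ground_indices)
    forward = v[ok][:, gi] @ w
    up = v[ok][:, traj.up_index]
    incl = np.degrees(np.arctan2(forward, -up))
    return float(incl.max() - incl.min())


def knee_rom(
    rec: StrideRecord,
    traj: Trajectory,
    max_invalid_fraction: float = 0.2,
) -> float:
    """Knee flexion ROM over the cycle (straight leg = 0 deg flexion)."""
    side = rec.side
    sl = _frame_slice(traj, rec.cycle_start_time, rec.cycle_end_time)
    hip = traj.get(f"{side}_hip")[sl]
    knee = traj.get(f"{side}_knee")[sl]
    ankle = traj.get(f"{side}_ankle")[sl]
    u = hip - knee
    v = ankle - knee
    ok = np.isfinite(u).all(axis=1) & np.isfinite(v).all(axis=1)
    if ok.size == 0 or (~ok).mean() > max_invalid_fraction or ok.sum() < 3:
        return float("nan")
    u, v = u[ok], v[ok]
    norms = np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        return float("nan")  # degenerate zero-length segment
    c = np.einsum("ij,ij->i", u, v) / norms
    interior = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    flexion = 180.0 - interior
    return float(flexion.max() - flexion.min())


# ---------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------

def summarize(
    strides: list[StrideRecord],
    min_strides_per_side: int = 3,
) -> ParameterSummary:
    """Aggregate stride records to mean, CV and side asymmetry.

    Mean and CV pool both sides; CV uses the sample (ddof=1) standard
    deviation and needs >= 2 values (and a nonzero mean). Asymmetry
    compares per-side means, requires ``min_strides_per_side`` valid
    strides on each side, and is bounded in [0, 100).
    """
    df = strides_to_frame(strides)
    n_left = int((df["side"] == "left").sum()) if len(df) else 0
    n_right = int((df["side"] == "right").sum()) if len(df) else 0
    rows = {}
    for p in PARAMETERS:
        vals = df[p].dropna() if len(df) else pd.Series(dtype=float)
        mean = float(vals.mean()) if len(vals) else float("nan")
        cv = float("nan")
        if len(vals) >= 2 and not math.isclose(mean, 0.0, abs_tol=1e-12):
            cv = 100.0 * float(vals.std(ddof=1)) / mean
        asym = float("nan")
        if len(df):
            lv = df.loc[df["side"] == "left", p].dropna()
            rv = df.loc[df["side"] == "right", p].dropna()
            if len(lv) >= min_strides_per_side and len(rv) >= min_strides_per_side:
                ml, mr = float(lv.mean()), float(rv.mean())
                hi, lo = max(ml, mr), min(ml, mr)
                if hi > 0:
                    asym = 100.0 * (1.0 - lo / hi)
        rows[p] = {"mean": mean, "cv_pct": cv, "asymmetry_pct": asym,
                   "n": int(len(vals))}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    return ParameterSummary(table, n_left, n_right)
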