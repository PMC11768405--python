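"""Readers and writers for keypoint, event and result files, plus
pinhole depth deprojection.

Keypoint CSV dialect: one row per frame, column ``time_s`` followed by
``<keypoint>_x, <keypoint>_y, <keypoint>_z`` per keypoint; NaN marks an
invalid sample. Keypoint JSON dialect: ``{"rate": Hz, "up_axis": ...,
"frames": [{"time": s, "keypoints": {label: [x, y, z] | null}}]}``.
Events are flat CSV (time_s, kind, side, x, y, z). All writers and
readers are mutual inverses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .events import GaitEvent
from .parameters import ParameterSummary, StrideRecord, strides_to_frame
from .skeleton import DEFAULT_SKELETON, SkeletonModel
from .trajectories import Trajectory

_AXES = ("x", "y", "z")


# ---------------------------------------------------------------------
# keypoint trajectories
# ---------------------------------------------------------------------

def write_keypoints_csv(traj: Trajectory, path: str | Path) -> None:
    data = {"time_s": traj.timestamps}
    for j, name in enumerate(traj.skeleton.keypoint_names):
        for ax in range(3):
            col = traj.positions[:, j, ax].copy()
            col[~traj.valid_mask[:, j]] = np.nan
            data[f"{name}_{_AXES[ax]}"] = col
    pd.DataFrame(data).to_csv(path, index=False)


def read_keypoints_csv(
    path: str | Path, skeleton: SkeletonModel | None = None,
    rate: float | None = None, up_axis: str = "z",
) -> Trajectory:
    skeleton = skeleton or DEFAULT_SKELETON
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing time_s column")
    missing = [
        name for name in skeleton.keypoint_names
        if any(f"{name}_{ax}" not in df.columns for ax in _AXES)
    ]
    if missing:
        raise ValueError(f"{path}: missing keypoint columns for {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    n, k = len(df), len(skeleton.keypoint_names)
    pos = np.empty((n, k, 3))
    for j, name in enumerate(skeleton.keypoint_names):
        for ax in range(3):
            pos[:, j, ax] = df[f"{name}_{_AXES[ax]}"].to_numpy(dtype=float)
    mask = np.isfinite(pos).all(axis=2)
    if rate is None:
        if n < 2:
            raise ValueError(f"{path}: cannot infer rate from {n} frames")
        rate = 1.0 / float(np.median(np.diff(t)))
    return Trajectory(t, pos, mask, rate, skeleton, up_axis)


def write_keypoints_json(traj: Trajectory, path: str | Path) -> None:
    frames = []
    for i in range(traj.n_frames):
        kps = {}
        for j, name in enumerate(traj.skeleton.keypoint_names):
            if traj.valid_mask[i, j]:
                kps[name] = [float(v) for v in traj.positions[i, j]]
            else:
                kps[name] = None
        frames.append({"time": float(traj.timestamps[i]), "keypoints": kps})
    payload = {"rate": traj.rate, "up_axis": traj.up_axis, "frames": frames}
    Path(path).write_text(json.dumps(payload))


def read_keypoints_json(
    path: str | Path, skeleton: SkeletonModel | None = None
) -> Trajectory:
    skeleton = skeleton or DEFAULT_SKELETON
    payload = json.loads(Path(path).read_text())
    frames = payload["frames"]
    n, k = len(frames), len(skeleton.keypoint_names)
    t = np.array([fr["time"] for fr in frames], dtype=float)
    pos = np.full((n, k, 3), np.nan)
    mask = np.zeros((n, k), dtype=bool)
    for i, fr in enumerate(frames):
        for j, name in enumerate(skeleton.keypoint_names):
            v = fr["keypoints"].get(name)
            if v is not None:
                pos[i, j] = v
                mask[i, j] = True
    return Trajectory(t, pos, mask, float(payload["rate"]), skeleton,
                      payload.get("up_axis", "z"))


def read_keypoints(path: str | Path, **kwargs) -> Trajectory:
    """Dispatch on file extension (.csv or .json)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return read_keypoints_csv(path, **kwargs)
    if suffix == ".json":
        return read_keypoints_json(path, **kwargs)
    raise ValueError(f"unsupported keypoint dialect: {suffix!r}")


# ---------------------------------------------------------------------
# events, strides, summaries
# ---------------------------------------------------------------------

def write_events_csv(events: list[GaitEvent], path: str | Path) -> None:
    rows = [
        {"time_s": e.time, "kind": e.kind, "side": e.side,
         "x": e.foot_position[0], "y": e.foot_position[1],
         "z": e.foot_position[2]}
        for e in events
    ]
    pd.DataFrame(rows, columns=["time_s", "kind", "side", "x", "y", "z"]
                 ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[GaitEvent]:
    df = pd.read_csv(path)
    required = {"time_s", "kind", "side", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: events CSV needs columns {sorted(required)}")
    return [
        GaitEvent(str(r.kind), str(r.side), float(r.time_s),
                  np.array([r.x, r.y, r.z], dtype=float))
        for r in df.itertuples()
    ]


def write_strides_csv(strides: list[StrideRecord], path: str | Path) -> None:
    strides_to_frame(strides).to_csv(path, index=False)


def write_summary_json(summary: ParameterSummary, path: str | Path) -> None:
    payload = {
        "n_strides_left": summary.n_strides_left,
        "n_strides_right": summary.n_strides_right,
        "parameters": {
            p: {k: (None if pd.isna(v) else float(v))
                for k, v in row.items()}
            for p, row in summary.table.iterrows()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------
# pinhole depth deprojection
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PinholeIntrinsics:
    """Pinhole camera intrinsics in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside image bounds")


def deproject(u, v, depth, intrinsics: PinholeIntrinsics):
    """Lift pixel coordinates + depth (m) to camera-frame 3D points.

    x = (u - cx) * depth / fx, y = (v - cy) * depth / fy, z = depth.
    Non-finite or non-positive depths yield NaN points (flagged, not
    raised). Accepts scalars or arrays; returns (points, valid).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    depth = np.asarray(depth, dtype=float)
    valid = np.isfinite(depth) & (depth > 0) & np.isfinite(u) & np.isfinite(v)
    d = np.where(valid, depth, np.nan)
    pts = np.stack(
        [(u - intrinsics.cx) * d / intrinsics.fx,
         (v - intrinsics.cy) * d / intrinsics.fy,
         d],
        axis=-1,
    )
    return pts, valid
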