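"""Keypoint trajectories and the preprocessing chain.

A :class:`Trajectory` holds timestamped 3D positions (meters) for the 17
skeleton keypoints together with a per-frame, per-keypoint validity mask.
Preprocessing follows a fixed order — resample to the working rate,
close short occlusion gaps by cubic-spline interpolation, then zero-phase
low-pass filter — so the filter never rings across unfilled gaps.

Filtering uses a 4th-order Butterworth low-pass (7 Hz default cutoff)
applied forward–backward (zero phase), so event timing downstream is not
lagged; the effective attenuation is the squared magnitude response.
Velocities are central differences on the uniform grid (one-sided at
segment edges), returned as per-frame Euclidean speed of the 3D
derivative, which makes every speed-based computation invariant to rigid
transforms of the world frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .skeleton import DEFAULT_SKELETON, SkeletonModel

log = logging.getLogger(__name__)

_UP_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class AnalysisWindow:
    """Half-open [start_time, end_time) slice of a recording to analyze."""

    start_time: float
    end_time: float

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise ValueError("end_time must exceed start_time")

    def contains(self, t: float) -> bool:
        return self.start_time <= t < self.end_time


@dataclass
class Trajectory:
    """Timestamped 17-keypoint 3D position series with validity mask.

    positions are meters, shape (n_frames, n_keypoints, 3); invalid
    samples are flagged in ``valid_mask`` (and NaN-filled), never
    silently zero.
    """

    timestamps: np.ndarray
    positions: np.ndarray
    valid_mask: np.ndarray
    rate: float
    skeleton: SkeletonModel = field(default_factory=lambda: DEFAULT_SKELETON)
    up_axis: str = "z"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        n = self.timestamps.shape[0]
        k = len(self.skeleton.keypoint_names)
        if self.positions.shape != (n, k, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({n}, {k}, 3)"
            )
        if self.valid_mask.shape != (n, k):
            raise ValueError("valid_mask shape mismatch")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.up_axis not in _UP_AXES:
            raise ValueError(f"up_axis must be one of {sorted(_UP_AXES)}")
        # invalid samples are NaN, never silently numeric
        self.positions = self.positions.copy()
        self.positions[~self.valid_mask] = np.nan

    # -- convenience -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.timestamps.shape[0]

    @property
    def up_index(self) -> int:
        return _UP_AXES[self.up_axis]

    @property
    def ground_indices(self) -> tuple[int, int]:
        return tuple(i for i in range(3) if i != self.up_index)  # type: ignore[return-value]

    def get(self, keypoint: str) -> np.ndarray:
        """(n_frames, 3) positions of one keypoint, NaN where invalid."""
        return self.positions[:, self.skeleton.index(keypoint), :]

    def mask(self, keypoint: str) -> np.ndarray:
        return self.valid_mask[:, self.skeleton.index(keypoint)]

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        if self.n_frames < 3:
            return True
        dt = np.diff(self.timestamps)
        return bool(np.all(np.abs(dt - dt.mean()) <= rtol * dt.mean()))


def _source_period(traj: Trajectory) -> float:
    if traj.n_frames < 2:
        raise ValueError("trajectory has fewer than 2 frames")
    return float(np.median(np.diff(traj.timestamps)))


def _valid_runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of contiguous True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    for a, b in zip(starts, stops):
        yield int(idx[a]), int(idx[b]) + 1


# ---------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------

def resample(traj: Trajectory, target_rate: float) -> Trajectory:
    """Interpolate the trajectory onto a uniform grid at ``target_rate``.

    Cubic-spline interpolation per keypoint coordinate. A resampled
    frame is valid only when bracketed by valid source frames no more
    than one source period apart (coincident valid frames count).
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if traj.n_frames == 0:
        raise ValueError("cannot resample an empty trajectory")
    period = _source_period(traj)
    if target_rate > 1.0 / period * (1 + 1e-9):
        log.warning(
            "upsampling from %.3f Hz to %.3f Hz", 1.0 / period, target_rate
        )
    t0, t1 = traj.timestamps[0], traj.timestamps[-1]
    n_new = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    new_t = t0 + np.arange(n_new) / target_rate

    k = len(traj.skeleton.keypoint_names)
    new_pos = np.full((n_new, k, 3), np.nan)
    new_mask = np.zeros((n_new, k), dtype=bool)
    gap_limit = period * (1 + 1e-6)

    for j in range(k):
        m = traj.valid_mask[:, j]
        tv = traj.timestamps[m]
        if tv.size < 2:
            log.warning(
                "keypoint %s has %d valid frames; left invalid after resampling",
                traj.skeleton.keypoint_names[j], tv.size,
            )
            continue
        spl = CubicSpline(tv, traj.positions[m, j, :], axis=0)
        # validity: bracketing valid source samples within one source period
        right = np.searchsorted(tv, new_t, side="left")
        ok = (right > 0) & (right < tv.size)
        prev = np.clip(right - 1, 0, tv.size - 1)
        nxt = np.clip(right, 0, tv.size - 1)
        bracket = np.zeros(n_new, dtype=bool)
        bracket[ok] = (tv[nxt[ok]] - tv[prev[ok]]) <= gap_limit
        exact = (right < tv.size) & np.isclose(
            new_t, tv[np.clip(right, 0, tv.size - 1)], rtol=0, atol=1e-9
        )
        valid = bracket | exact
        new_mask[valid, j] = True
        new_pos[valid, j, :] = spl(new_t[valid])

    return Trajectory(new_t, new_pos, new_mask, float(target_rate),
                      traj.skeleton, traj.up_axis)


def fill_gaps(traj: Trajectory, max_gap: float = 0.250) -> Trajectory:
    """Close short invalid runs by cubic-spline interpolation.

    A run of invalid frames is filled only if it is strictly shorter
    than ``max_gap`` seconds and has valid data on both sides; longer
    gaps and edge gaps stay invalid (cubic extrapolation is unstable).
    Valid samples are never modified.
    """
    if not traj.is_uniform():
        raise ValueError("fill_gaps requires uniform sampling")
    dt = _source_period(traj)
    pos = traj.positions.copy()
    mask = traj.valid_mask.copy()
    for j in range(mask.shape[1]):
        m = mask[:, j]
        if m.all() or m.sum() < 2:
            continue
        tv = traj.timestamps[m]
        spl = None
        invalid = ~m
        for a, b in _valid_runs(invalid):
            if a == 0 or b == mask.shape[0]:
                continue  # edge gap: never extrapolated
            if (b - a) * dt >= max_gap:
                continue
            if spl is None:
                spl = CubicSpline(tv, traj.positions[m, j, :], axis=0)
            pos[a:b, j, :] = spl(traj.timestamps[a:b])
            mask[a:b, j] = True
    return Trajectory(traj.timestamps.copy(), pos, mask, traj.rate,
                      traj.skeleton, traj.up_axis)


def lowpass_filter(traj: Trajectory, order: int = 4, cutoff: float = 7.0) -> Trajectory:
    """Zero-phase Butterworth low-pass, per contiguous valid segment.

    Each coordinate series is filtered independently; invalid gaps are
    never filtered across. Segments shorter than the filter warm-up
    length pass through unfiltered with a logged warning.
    """
    if not traj.is_uniform():
        raise ValueError("lowpass_filter requires uniform sampling")
    if cutoff >= traj.rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below Nyquist ({traj.rate / 2} Hz)"
        )
    b, a = butter(order, cutoff, fs=traj.rate)
    padlen = 3 * max(len(a), len(b))  # filtfilt default
    pos = traj.positions.copy()
    for j in range(traj.valid_mask.shape[1]):
        for s, e in _valid_runs(traj.valid_mask[:, j]):
            if e - s <= padlen:
                log.warning(
                    "segment of %d frames (keypoint %s) shorter than filter "
                    "warm-up; passed through unfiltered",
                    e - s, traj.skeleton.keypoint_names[j],
                )
                continue
            pos[s:e, j, :] = filtfilt(b, a, traj.positions[s:e, j, :], axis=0)
    return Trajectory(traj.timestamps.copy(), pos, traj.valid_mask.copy(),
                      traj.rate, traj.skeleton, traj.up_axis)


def velocity(traj: Trajectory, keypoint: str) -> np.ndarray:
    """Per-frame speed (m/s): Euclidean norm of the 3D derivative.

    Central differences in the interior of each contiguous valid
    segment, one-sided at segment edges; NaN inside invalid gaps.
    """
    m = traj.mask(keypoint)
    if m.sum() < 3:
        raise ValueError(
            f"fewer than 3 valid frames for keypoint {keypoint!r}"
        )
    p = traj.get(keypoint)
    speed = np.full(traj.n_frames, np.nan)
    for s, e in _valid_runs(m):
        if e - s < 2:
            continue
        d = np.gradient(p[s:e], traj.timestamps[s:e], axis=0)
        speed[s:e] = np.linalg.norm(d, axis=1)
    return speed


def clip_to_windows(traj: Trajectory, windows: list[AnalysisWindow]) -> Trajectory:
    """Invalidate every frame outside all analysis windows."""
    ws = sorted(windows, key=lambda w: w.start_time)
    for w1, w2 in zip(ws, ws[1:]):
        if w2.start_time < w1.end_time:
            raise ValueError("analysis windows must be non-overlapping")
    keep = np.zeros(traj.n_frames, dtype=bool)
    t0, t1 = traj.timestamps[0], traj.timestamps[-1]
    for w in ws:
        if w.end_time <= t0 or w.start_time > t1:
            log.warning("window [%s, %s) outside time range; skipped",
                        w.start_time, w.end_time)
            continue
        keep |= (traj.timestamps >= w.start_time) & (traj.timestamps < w.end_time)
    mask = traj.valid_mask & keep[:, None]
    return Trajectory(traj.timestamps.copy(), traj.positions.copy(), mask,
                      traj.rate, traj.skeleton, traj.up_axis)


def preprocess(
    traj: Trajectory,
    target_rate: float = 30.0,
    max_gap: float = 0.250,
    filter_order: int = 4,
    filter_cutoff: float = 7.0,
    windows: list[AnalysisWindow] | None = None,
) -> Trajectory:
    """Standard chain: resample -> fill gaps -> low-pass -> (clip)."""
    out = resample(traj, target_rate)
    out = fill_gaps(out, max_gap=max_gap)
    out = lowpass_filter(out, order=filter_order, cutoff=filter_cutoff)
    if windows:
        out = clip_to_windows(out, windows)
    return out
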