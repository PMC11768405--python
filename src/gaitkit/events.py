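"""Adaptive-threshold detection of initial and final foot contacts.

Initial contact (IC, heel strike) is detected where the 3D heel speed
drops below ``ic_factor`` (default 0.5) times the walking speed; final
contact (FC, toe-off) where the 3D toe speed rises above ``fc_factor``
(default 0.8) times the walking speed. Because the toe is quasi-static
during stance and accelerates out of it, the upward crossing anchors
toe-off; the downward crossing anchors heel strike.

The thresholds adapt to the walker: detection runs twice, first with a
nominal walking speed of 1 m/s, then with a speed re-estimated from the
first-pass IC times and heel positions (median of per-stride
displacement / duration, robust to turning strides). Crossing times are
refined below the frame grid by linear interpolation of the speed
series, which matters at 30 Hz sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trajectories import Trajectory, velocity

log = logging.getLogger(__name__)

IC = "IC"
FC = "FC"


@dataclass
class GaitEvent:
    """A typed, sided foot-contact instant.

    ``foot_position`` is the heel position for IC and the toe position
    for FC, at event time. ``margin`` records how decisively the speed
    series cleared the threshold (relative depth of the excursion past
    it) and is used only to arbitrate duplicate events during cleanup.
    """

    kind: str
    side: str
    time: float
    foot_position: np.ndarray
    margin: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind not in (IC, FC):
            raise ValueError(f"kind must be 'IC' or 'FC', got {self.kind!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.foot_position = np.asarray(self.foot_position, dtype=float)


@dataclass
class DetectionConfig:
    """Tunables of the two-pass adaptive-threshold detector."""

    ic_factor: float = 0.5
    fc_factor: float = 0.8
    initial_speed: float = 1.0
    n_passes: int = 2
    min_event_separation: float = 0.4

    def __post_init__(self) -> None:
        if not self.initial_speed > 0:
            raise ValueError("initial_speed must be positive")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        if self.ic_factor <= 0 or self.fc_factor <= 0:
            raise ValueError("threshold factors must be positive")


def _interp_position(traj: Trajectory, keypoint: str, t: float) -> np.ndarray:
    """Linear interpolation of a keypoint position at time t."""
    ts = traj.timestamps
    i = int(np.searchsorted(ts, t, side="right")) - 1
    i = max(0, min(i, traj.n_frames - 2))
    p = traj.get(keypoint)
    w = (t - ts[i]) / (ts[i + 1] - ts[i])
    w = min(max(w, 0.0), 1.0)
    return (1 - w) * p[i] + w * p[i + 1]


def _detect_crossings(
    traj: Trajectory,
    keypoint: str,
    threshold: float,
    direction: str,
    kind: str,
    side: str,
    min_separation: float,
) -> list[GaitEvent]:
    speed = velocity(traj, keypoint)
    ts = traj.timestamps
    if direction == "down":
        sig = -speed
        thr = -threshold
    else:
        sig = speed
        thr = threshold
    events: list[GaitEvent] = []
    prev, cur = sig[:-1], sig[1:]
    hits = np.flatnonzero(
        np.isfinite(prev) & np.isfinite(cur) & (prev <= thr) & (cur > thr)
    )
    for i in hits:
        # sub-frame refinement: linear interpolation of the crossing
        frac = (thr - sig[i]) / (sig[i + 1] - sig[i])
        t_star = ts[i] + frac * (ts[i + 1] - ts[i])
        if events and t_star - events[-1].time < min_separation:
            continue  # debounce: keep the earlier crossing
        # margin: deepest excursion past the threshold before recrossing
        j = i + 1
        peak = sig[j]
        while j < sig.size and np.isfinite(sig[j]) and sig[j] > thr:
            peak = max(peak, sig[j])
            j += 1
        margin = (peak - thr) / max(abs(thr), 1e-12)
        events.append(
            GaitEvent(kind, side, float(t_star),
                      _interp_position(traj, keypoint, float(t_star)),
                      float(margin))
        )
    if not events:
        log.info("no %s crossings for %s %s", direction, side, kind)
    return events


def detect_ic(
    traj: Trajectory, side: str, walking_speed: float,
    cfg: DetectionConfig | None = None,
) -> list[GaitEvent]:
    """ICs: downward crossings of heel speed through ic_factor * speed."""
    cfg = cfg or DetectionConfig()
    if not walking_speed > 0:
        raise ValueError("walking_speed must be positive")
    heel = traj.skeleton.heel(side)
    return _detect_crossings(
        traj, heel, cfg.ic_factor * walking_speed, "down", IC, side,
        cfg.min_event_separation,
    )


def detect_fc(
    traj: Trajectory, side: str, walking_speed: float,
    cfg: DetectionConfig | None = None,
) -> list[GaitEvent]:
    """FCs: upward crossings of toe speed through fc_factor * speed."""
    cfg = cfg or DetectionConfig()
    if not walking_speed > 0:
        raise ValueError("walking_speed must be positive")
    toe = traj.skeleton.toe(side)
    return _detect_crossings(
        traj, toe, cfg.fc_factor * walking_speed, "up", FC, side,
        cfg.min_event_separation,
    )


def estimate_walking_speed(
    ics: list[GaitEvent], fallback: float = 1.0
) -> float:
    """Median stride speed over successive same-side IC pairs.

    Speed of one stride = Euclidean distance between the two heel
    positions / time difference. Falls back to ``fallback`` (with a
    warning) when fewer than two ICs exist on both sides.
    """
    speeds: list[float] = []
    for side in ("left", "right"):
        side_ics = sorted((e for e in ics if e.side == side),
                          key=lambda e: e.time)
        for a, b in zip(side_ics, side_ics[1:]):
            dt = b.time - a.time
            if dt > 0:
                d = float(np.linalg.norm(b.foot_position - a.foot_position))
                speeds.append(d / dt)
    if not speeds:
        log.warning("fewer than 2 ICs per side; falling back to %.2f m/s",
                    fallback)
        return fallback
    return float(np.median(speeds))


def _clean_alternation(events: list[GaitEvent]) -> list[GaitEvent]:
    """Enforce IC/FC alternation per side; drop the weaker duplicate."""
    out: list[GaitEvent] = []
    for side in ("left", "right"):
        seq = sorted((e for e in events if e.side == side),
                     key=lambda e: e.time)
        kept: list[GaitEvent] = []
        for ev in seq:
            if kept and kept[-1].kind == ev.kind:
                prev = kept[-1]
                # keep the stronger threshold margin; tie -> earlier event
                if np.nan_to_num(ev.margin) > np.nan_to_num(prev.margin):
                    log.info("dropping duplicate %s %s at %.3f s (weaker margin)",
                             side, prev.kind, prev.time)
                    kept[-1] = ev
                else:
                    log.info("dropping duplicate %s %s at %.3f s (weaker margin)",
                             side, ev.kind, ev.time)
                continue
            kept.append(ev)
        out.extend(kept)
    return sorted(out, key=lambda e: e.time)


def detect_events(
    traj: Trajectory, cfg: DetectionConfig | None = None
) -> list[GaitEvent]:
    """Two-pass detection of all ICs and FCs, both sides, sorted by time.

    Pass 1 runs with ``cfg.initial_speed``; the walking speed is then
    re-estimated from the pass-1 ICs and the detector re-run. After the
    final pass, per-side sequences are cleaned so IC and FC alternate
    (orphan duplicates dropped by threshold margin).
    """
    cfg = cfg or DetectionConfig()
    speed = cfg.initial_speed
    ics: list[GaitEvent] = []
    for p in range(cfg.n_passes):
        ics = []
        for side in ("left", "right"):
            ics.extend(detect_ic(traj, side, speed, cfg))
        if p < cfg.n_passes - 1:
            speed = estimate_walking_speed(ics, fallback=cfg.initial_speed)
    events = list(ics)
    for side in ("left", "right"):
        events.extend(detect_fc(traj, side, speed, cfg))
    return _clean_alternation(events)
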