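"""Skeleton model: the 17 body keypoints used throughout the pipeline.

The keypoint set covers head, shoulders, elbows, wrists, hips, knees,
ankles, heels and big toes — every landmark any downstream gait
computation needs (heel/toe velocity for contact detection, hip–knee–ankle
for knee flexion, shoulder–wrist for arm swing). Names follow the
COCO-WholeBody convention (``left_heel``, ``right_big_toe``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field


KEYPOINT_NAMES: tuple[str, ...] = (
    "head",
    "left_shoulder", "right_shoulder",
    "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_heel", "right_heel",
    "left_big_toe", "right_big_toe",
)

SIDES = ("left", "right")


def _default_side_map() -> dict[str, str]:
    out = {}
    for name in KEYPOINT_NAMES:
        if name.startswith("left_"):
            out[name] = "left"
        elif name.startswith("right_"):
            out[name] = "right"
        else:
            out[name] = "center"
    return out


def _default_segment_pairs() -> dict[str, list[tuple[str, str]]]:
    pairs: dict[str, list[tuple[str, str]]] = {}
    for s in SIDES:
        pairs[s] = [
            (f"{s}_shoulder", f"{s}_wrist"),
            (f"{s}_hip", f"{s}_knee"),
            (f"{s}_knee", f"{s}_ankle"),
            (f"{s}_heel", f"{s}_big_toe"),
        ]
    return pairs


@dataclass(frozen=True)
class SkeletonModel:
    """Ordered keypoint labels plus side and segment metadata.

    Invariants enforced at construction: exactly 17 labels, every label
    has a side assignment, heel and big-toe labels exist for both sides
    (required by contact detection), and segment endpoints are labels.
    """

    keypoint_names: tuple[str, ...] = KEYPOINT_NAMES
    side_map: dict[str, str] = field(default_factory=_default_side_map)
    segment_pairs: dict[str, list[tuple[str, str]]] = field(
        default_factory=_default_segment_pairs
    )

    def __post_init__(self) -> None:
        names = tuple(self.keypoint_names)
        if len(names) != 17:
            raise ValueError(f"expected 17 keypoints, got {len(names)}")
        if len(set(names)) != 17:
            raise ValueError("keypoint names must be unique")
        missing_side = [n for n in names if n not in self.side_map]
        if missing_side:
            raise ValueError(f"keypoints without side assignment: {missing_side}")
        for side in SIDES:
            for part in ("heel", "big_toe"):
                if f"{side}_{part}" not in names:
                    raise ValueError(f"required keypoint {side}_{part} missing")
        for side, segs in self.segment_pairs.items():
            for a, b in segs:
                if a not in names or b not in names:
                    raise ValueError(f"segment ({a}, {b}) references unknown keypoint")
        object.__setattr__(self, "keypoint_names", names)

    def index(self, name: str) -> int:
        try:
            return self.keypoint_names.index(name)
        except ValueError:
            raise KeyError(f"unknown keypoint {name!r}") from None

    def heel(self, side: str) -> str:
        return f"{side}_heel"

    def toe(self, side: str) -> str:
        return f"{side}_big_toe"

    def side_of(self, name: str) -> str:
        return self.side_map[name]


DEFAULT_SKELETON = SkeletonModel()
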