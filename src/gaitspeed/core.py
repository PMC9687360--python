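"""Shared domain types for the gait silhouette pipeline.

The pipeline's unit of study is a *walking sequence*: an ordered stack of
binary (foreground/background) silhouette frames of one participant walking
on a treadmill at a known speed. Speeds between 2 and 7 km/h are bucketed
into three classes — slow (2–3), normal (4–5) and fast (6–7 km/h).

From every frame five dimensionless, camera-distance-independent body
measurements are extracted (canonical order fixed package-wide):

    HW1  full-body height / full-body width
    HW2  full-body height / mid-body width
    HW3  full-body height / lower-body width
    A1   apparent-body (foreground) area / full-body bounding-box area
    A2   area between the two legs / full-body bounding-box area
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Canonical feature order used everywhere (signal rows, pattern rows, reports).
FEATURE_NAMES: tuple[str, ...] = ("HW1", "HW2", "HW3", "A1", "A2")

#: Index of each feature name in the canonical order.
FEATURE_INDEX: dict[str, int] = {name: i for i, name in enumerate(FEATURE_NAMES)}


class SpeedClass(str, enum.Enum):
    """Three-way walking-speed category."""

    SLOW = "slow"
    NORMAL = "normal"
    FAST = "fast"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed class order for labels/reports.
SPEED_CLASSES: tuple[SpeedClass, ...] = (SpeedClass.SLOW, SpeedClass.NORMAL, SpeedClass.FAST)


def speed_class_of(speed_kmh: float) -> SpeedClass:
    """Bucket a treadmill speed into slow (2–3), normal (4–5) or fast (6–7 km/h)."""
    if not 2.0 <= speed_kmh <= 7.0:
        raise ValueError(f"speed_kmh must be in [2, 7], got {speed_kmh}")
    if speed_kmh < 3.5:
        return SpeedClass.SLOW
    if speed_kmh < 5.5:
        return SpeedClass.NORMAL
    return SpeedClass.FAST


@dataclass
class SilhouetteSequence:
    """Ordered binary frames for one participant at one treadmill speed.

    ``frames`` holds 2-D boolean masks (foreground = True), all the same shape.
    """

    frames: list[np.ndarray]
    fps: float
    participant_id: str
    speed_kmh: float
    speed_class: SpeedClass = field(init=False)

    def __post_init__(self) -> None:
        self.speed_class = speed_class_of(self.speed_kmh)
        if not self.frames:
            raise ValueError("sequence must contain at least one frame")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class FeatureSignalSet:
    """The five per-frame ratio signals for one sequence, rows in canonical order."""

    signals: np.ndarray  # shape (5, T)
    fps: float
    participant_id: str
    speed_class: SpeedClass
    speed_kmh: float | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] != len(FEATURE_NAMES):
            raise ValueError(f"signals must be 5 x T, got shape {self.signals.shape}")

    @property
    def n_frames(self) -> int:
        return self.signals.shape[1]

    def signal(self, feature: str) -> np.ndarray:
        """Return one named feature signal (view)."""
        return self.signals[FEATURE_INDEX[feature]]


def validate_subset(subset: Sequence[str]) -> tuple[str, ...]:
    """Canonicalize a feature subset: known names, no duplicates, canonical order."""
    names = list(subset)
    unknown = [n for n in names if n not in FEATURE_INDEX]
    if unknown:
        raise ValueError(f"unknown feature name(s): {unknown}")
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate feature(s) in subset: {names}")
    if not names:
        raise ValueError("subset must be non-empty")
    return tuple(sorted(names, key=FEATURE_INDEX.__getitem__))
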