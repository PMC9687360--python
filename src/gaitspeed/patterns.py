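"""Fixed-length labelled walk patterns and feature-combination datasets.

A *walk pattern* is the classifier's unit of input: an ``n_features x 240``
matrix (one row per selected ratio signal, truncated to the first 240
frames) labelled with the sequence's speed class and participant. Restricting
all patterns of a cohort to one feature subset gives a *combination
dataset*; enumerating every unordered subset of sizes 1–4 of the five
measurements yields C(5,1)+C(5,2)+C(5,3)+C(5,4) = 5+10+10+5 = 30 such
datasets, plus the all-five baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .core import (
    FEATURE_INDEX,
    FEATURE_NAMES,
    FeatureSignalSet,
    SpeedClass,
    validate_subset,
)

__all__ = [
    "WalkPattern",
    "CombinationDataset",
    "PATTERN_LENGTH",
    "enumerate_combinations",
    "make_walk_pattern",
    "build_combination_dataset",
]

#: Default pattern length in frames (the cohort's minimum sequence length).
PATTERN_LENGTH = 240


@dataclass
class WalkPattern:
    """One labelled fixed-length multichannel pattern."""

    matrix: np.ndarray  # (n_features, length)
    label: SpeedClass
    participant_id: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.features):
            raise ValueError("pattern matrix rows must match the feature subset")


@dataclass
class CombinationDataset:
    """All walk patterns of a cohort restricted to one feature subset."""

    feature_subset: tuple[str, ...]
    patterns: list[WalkPattern]

    @property
    def n_features(self) -> int:
        return len(self.feature_subset)

    def class_counts(self) -> dict[SpeedClass, int]:
        counts: dict[SpeedClass, int] = {}
        for p in self.patterns:
            counts[p.label] = counts.get(p.label, 0) + 1
        return counts

    def participants(self) -> list[str]:
        return sorted({p.participant_id for p in self.patterns})


def enumerate_combinations(
    n_total: int = 5, sizes: Iterable[int] = (1, 2, 3, 4)
) -> list[tuple[str, ...]]:
    """All unordered feature subsets of the requested sizes.

    Order is deterministic: by subset size, then lexicographically in the
    canonical feature order — so repeated runs and reports line up.
    """
    sizes = sorted(set(sizes))
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if any(s < 1 or s > n_total for s in sizes):
        raise ValueError(f"sizes must lie in [1, {n_total}], got {sizes}")
    names = FEATURE_NAMES[:n_total]
    out: list[tuple[str, ...]] = []
    for size in sizes:
        out.extend(combinations(names, size))
    return out


def make_walk_pattern(
    signals: FeatureSignalSet,
    subset: Sequence[str],
    length: int = PATTERN_LENGTH,
) -> WalkPattern:
    """Cut one pattern from a sequence's signals: subset rows, first ``length`` frames."""
    subset = validate_subset(subset)
    if signals.n_frames < length:
        raise ValueError(
            f"sequence has {signals.n_frames} frames, shorter than pattern length {length}"
        )
    rows = [FEATURE_INDEX[name] for name in subset]
    return WalkPattern(
        matrix=signals.signals[rows, :length].copy(),
        label=signals.speed_class,
        participant_id=signals.participant_id,
        features=subset,
    )


def build_combination_dataset(
    all_signals: Iterable[FeatureSignalSet],
    subset: Sequence[str],
    length: int = PATTERN_LENGTH,
) -> CombinationDataset:
    """One pattern per sequence, all restricted to ``subset``."""
    subset = validate_subset(subset)
    patterns = [make_walk_pattern(s, subset, length) for s in all_signals]
    if not patterns:
        raise ValueError("no sequences supplied")
    return CombinationDataset(feature_subset=subset, patterns=patterns)
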