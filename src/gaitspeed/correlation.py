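"""Pairwise R² between the five measurements, per speed condition.

The screening statistic is the coefficient of determination — the squared
Pearson correlation — computed between every pair of ratio signals within
one speed class. Values are banded on the conventional interpretation
scale: weak 0.10–0.39, moderate 0.40–0.69, strong 0.70–0.89, very strong
0.90–1.00 (values below 0.10 get an explicit ``below_weak`` label). A
feature subset counts as *low-correlation* when every within-subset pair
falls below the moderate band's lower edge (R² < 0.40) — redundant feature
pairs are exactly the highly correlated ones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import FEATURE_INDEX, FEATURE_NAMES, FeatureSignalSet, SpeedClass, validate_subset

__all__ = [
    "CorrelationBand",
    "CorrelationMatrix",
    "r_squared",
    "band_of",
    "correlation_matrix",
    "low_correlation_subset",
    "LOW_CORRELATION_CUTOFF",
]

#: Default cutoff for "low correlation": below the moderate band's lower edge.
LOW_CORRELATION_CUTOFF = 0.40


class CorrelationBand(str, enum.Enum):
    BELOW_WEAK = "below_weak"
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def band_of(r2: float) -> CorrelationBand:
    """Band an R² value; printed interval endpoints are inclusive, upper band wins ties."""
    if not 0.0 <= r2 <= 1.0 + 1e-12:
        raise ValueError(f"R^2 must lie in [0, 1], got {r2}")
    if r2 < 0.10:
        return CorrelationBand.BELOW_WEAK
    if r2 < 0.40:
        return CorrelationBand.WEAK
    if r2 < 0.70:
        return CorrelationBand.MODERATE
    if r2 < 0.90:
        return CorrelationBand.STRONG
    return CorrelationBand.VERY_STRONG


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination: the squared Pearson correlation of x and y.

    Symmetric and invariant under affine rescaling of either series; equals
    1 − SS_res/SS_tot of the simple linear regression of y on x.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("undefined correlation: a series has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return min(r * r, 1.0)


@dataclass
class CorrelationMatrix:
    """5×5 R² matrix for one speed class, with interpretation bands."""

    speed_class: SpeedClass
    r2: np.ndarray  # (5, 5), symmetric, unit diagonal

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(FEATURE_NAMES)
        if self.r2.shape != (n, n):
            raise ValueError(f"r2 must be {n}x{n}")

    @property
    def bands(self) -> np.ndarray:
        return np.array(
            [[band_of(v).value for v in row] for row in self.r2], dtype=object
        )

    def pair(self, a: str, b: str) -> float:
        return float(self.r2[FEATURE_INDEX[a], FEATURE_INDEX[b]])


def correlation_matrix(
    signals: Iterable[FeatureSignalSet],
    pooling: str = "concatenate",
) -> CorrelationMatrix:
    """Pairwise R² among the five measurements over one speed class.

    ``pooling='concatenate'`` (default) joins all sequences' frames per
    feature before correlating; ``pooling='per_sequence'`` computes R² per
    sequence and averages — kept as a sensitivity check.
    """
    sets = list(signals)
    if not sets:
        raise ValueError("need at least one sequence")
    classes = {s.speed_class for s in sets}
    if len(classes) != 1:
        raise ValueError(f"sequences span multiple speed classes: {sorted(c.value for c in classes)}")
    n = len(FEATURE_NAMES)
    if pooling == "concatenate":
        data = np.concatenate([s.signals for s in sets], axis=1)
        r2 = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                r2[i, j] = r2[j, i] = r_squared(data[i], data[j])
    elif pooling == "per_sequence":
        stack = np.stack(
            [
                [
                    [1.0 if i == j else r_squared(s.signals[i], s.signals[j]) for j in range(n)]
                    for i in range(n)
                ]
                for s in sets
            ]
        )
        r2 = stack.mean(axis=0)
    else:
        raise ValueError(f"unknown pooling strategy: {pooling!r}")
    return CorrelationMatrix(speed_class=sets[0].speed_class, r2=r2)


def low_correlation_subset(
    matrix: CorrelationMatrix,
    subset: Sequence[str],
    cutoff: float = LOW_CORRELATION_CUTOFF,
) -> bool:
    """True iff every within-subset pair has R² strictly below ``cutoff``.

    Singleton subsets are vacuously low-correlation.
    """
    subset = validate_subset(subset)
    idx = [FEATURE_INDEX[f] for f in subset]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if matrix.r2[idx[a], idx[b]] >= cutoff:
                return False
    return True
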