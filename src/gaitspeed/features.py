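"""Per-frame ratio-based body measurements from binary silhouettes.

Given a binary silhouette mask, a tight bounding box around the foreground
defines the full-body height H and width W1. Two horizontal bands of the box
(mid-body and lower-body, by default the middle and bottom thirds) give the
band widths W2 and W3 as horizontal *extents* — the distance between the
outermost foreground pixels of a row, maximized over the band's rows — so
that a spread leg pose widens W3 even though the space between the legs is
background. The five ratios are then

    HW1 = H / W1,   HW2 = H / W2,   HW3 = H / W3,
    A1  = (foreground pixels in box) / (H * W1),
    A2  = (background pixels between the outermost foreground runs of each
           row, summed over the box) / (H * W1).

Rows with a single foreground run (head, torso, merged legs) contribute
nothing to A2, so its numerator is exactly the enclosed inter-leg gap and
A1 + A2 <= 1 always, with equality for a silhouette whose only concavity
is the space between the legs.

All five are dimensionless, hence insensitive to the subject-to-camera
distance (up to rasterization error) and to translation of the silhouette
within the frame.

Coordinates are 0-based and row-major with y increasing downward; boxes and
band row intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .core import FEATURE_NAMES, FeatureSignalSet, SilhouetteSequence

__all__ = [
    "BoundingBox",
    "FrameFeatures",
    "FeatureConfig",
    "DegenerateFrameError",
    "SequenceRejectedError",
    "binarize_frame",
    "full_body_bbox",
    "band_width",
    "inter_leg_area",
    "extract_frame_features",
    "extract_sequence_features",
]


class DegenerateFrameError(ValueError):
    """Raised when a frame (or a required band) contains no foreground."""


class SequenceRejectedError(ValueError):
    """Raised when too many frames of a sequence are degenerate to repair."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box; rows [top_row, top_row+height), cols [left_col, left_col+width)."""

    top_row: int
    left_col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("bounding box must have height >= 1 and width >= 1")


@dataclass(frozen=True)
class FrameFeatures:
    """The five ratios of a single frame (see module docstring)."""

    hw1: float
    hw2: float
    hw3: float
    a1: float
    a2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.hw1, self.hw2, self.hw3, self.a1, self.a2], dtype=float)


@dataclass(frozen=True)
class FeatureConfig:
    """Band extents and cleaning options for feature extraction.

    ``mid_band`` and ``low_band`` are fraction intervals of the full-body
    bounding-box height, measured from the top, half-open. The thirds
    defaults approximate a head+torso / hip / leg partition of the body.
    ``max_degenerate_frac`` bounds the fraction of empty frames a sequence
    may contain before it is rejected instead of repaired by interpolation.
    """

    mid_band: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    low_band: tuple[float, float] = (2.0 / 3.0, 1.0)
    a2_band: tuple[float, float] = (0.0, 1.0)
    clean_small_components: bool = False
    min_component_frac: float = 0.005
    max_degenerate_frac: float = 0.10

    def __post_init__(self) -> None:
        for band in (self.mid_band, self.low_band, self.a2_band):
            lo, hi = band
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"band must satisfy 0 <= lo < hi <= 1, got {band}")


def binarize_frame(image: np.ndarray, threshold: float = 127) -> np.ndarray:
    """Threshold a grayscale frame into a boolean foreground mask.

    Foreground is where intensity strictly exceeds ``threshold`` (default 127,
    the midpoint of 8-bit intensities). Boolean input is passed through
    unchanged, making the operation idempotent.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot binarize an empty image")
    if image.dtype == bool:
        return image.copy()
    return image > threshold


def clean_mask(mask: np.ndarray, min_component_frac: float = 0.005) -> np.ndarray:
    """Drop 8-connected foreground specks smaller than a fraction of the largest blob."""
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_component_frac * sizes.max()) + 1
    return np.isin(labels, keep)


def full_body_bbox(mask: np.ndarray) -> BoundingBox:
    """Tightest axis-aligned box around all foreground pixels."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        raise DegenerateFrameError("mask has no foreground pixels")
    cols = np.flatnonzero(mask.any(axis=0))
    return BoundingBox(
        top_row=int(rows[0]),
        left_col=int(cols[0]),
        height=int(rows[-1] - rows[0] + 1),
        width=int(cols[-1] - cols[0] + 1),
    )


def _band_rows(box: BoundingBox, band: tuple[float, float]) -> tuple[int, int]:
    """Absolute half-open row interval of a fractional band of the box height."""
    lo, hi = band
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"band must satisfy 0 <= lo < hi <= 1, got {band}")
    r0 = box.top_row + int(np.floor(lo * box.height))
    r1 = box.top_row + int(np.floor(hi * box.height))
    return r0, max(r1, r0 + 1)


def _row_extents(mask: np.ndarray, r0: int, r1: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row (has_fg, first_col, last_col) for rows [r0, r1)."""
    band = np.asarray(mask[r0:r1], dtype=bool)
    has = band.any(axis=1)
    w = band.shape[1]
    first = band.argmax(axis=1)
    last = w - 1 - band[:, ::-1].argmax(axis=1)
    return has, first, last


def band_width(mask: np.ndarray, box: BoundingBox, band: tuple[float, float]) -> int:
    """Maximum horizontal extent (rightmost − leftmost + 1) over the band's rows.

    This is the *extent*, not the foreground count: background gaps between
    the legs lie inside the extent and therefore widen it.
    """
    r0, r1 = _band_rows(box, band)
    has, first, last = _row_extents(mask, r0, r1)
    if not has.any():
        raise DegenerateFrameError(f"no foreground in band rows [{r0}, {r1})")
    return int((last[has] - first[has] + 1).max())


def inter_leg_area(mask: np.ndarray, box: BoundingBox, band: tuple[float, float]) -> int:
    """Background pixels strictly between the outermost foreground runs, summed over band rows.

    Rows with a single run (legs merged) or no foreground contribute zero.
    """
    r0, r1 = _band_rows(box, band)
    band_mask = np.asarray(mask[r0:r1], dtype=bool)
    has, first, last = _row_extents(mask, r0, r1)
    extent = last - first + 1
    counts = band_mask.sum(axis=1)
    gaps = np.where(has, extent - counts, 0)
    return int(gaps.sum())


def extract_frame_features(mask: np.ndarray, config: FeatureConfig | None = None) -> FrameFeatures:
    """Compute the five ratios for one silhouette frame.

    Raises :class:`DegenerateFrameError` when the frame or a required band is
    empty; sequence-level extraction repairs such frames by interpolation.
    """
    config = config or FeatureConfig()
    mask = np.asarray(mask, dtype=bool)
    if config.clean_small_components:
        mask = clean_mask(mask, config.min_component_frac)
    box = full_body_bbox(mask)
    h, w1 = box.height, box.width
    w2 = band_width(mask, box, config.mid_band)
    w3 = band_width(mask, box, config.low_band)
    box_area = h * w1
    fg_in_box = int(
        mask[box.top_row : box.top_row + h, box.left_col : box.left_col + w1].sum()
    )
    between_legs = inter_leg_area(mask, box, config.a2_band)
    return FrameFeatures(
        hw1=h / w1,
        hw2=h / w2,
        hw3=h / w3,
        a1=fg_in_box / box_area,
        a2=between_legs / box_area,
    )


def _interpolate_missing(signals: np.ndarray) -> np.ndarray:
    """Fill NaN columns by per-row linear interpolation (edge values extended)."""
    out = signals.copy()
    t = np.arange(signals.shape[1])
    for i in range(out.shape[0]):
        bad = np.isnan(out[i])
        if bad.any():
            out[i, bad] = np.interp(t[bad], t[~bad], out[i, ~bad])
    return out


def extract_sequence_features(
    seq: SilhouetteSequence, config: FeatureConfig | None = None
) -> FeatureSignalSet:
    """Extract the five ratio signals for every frame of a sequence.

    Degenerate frames are marked missing and repaired by linear interpolation
    from their neighbours; a sequence whose degenerate fraction exceeds
    ``config.max_degenerate_frac`` is rejected outright.
    """
    config = config or FeatureConfig()
    t_total = len(seq.frames)
    signals = np.full((len(FEATURE_NAMES), t_total), np.nan)
    n_bad = 0
    for t, frame in enumerate(seq.frames):
        try:
            signals[:, t] = extract_frame_features(frame, config).as_array()
        except DegenerateFrameError:
            n_bad += 1
    if n_bad == t_total:
        raise SequenceRejectedError("every frame of the sequence is degenerate")
    if n_bad > config.max_degenerate_frac * t_total:
        raise SequenceRejectedError(
            f"{n_bad}/{t_total} degenerate frames exceeds the "
            f"{config.max_degenerate_frac:.0%} repair limit"
        )
    if n_bad:
        signals = _interpolate_missing(signals)
    return FeatureSignalSet(
        signals=signals,
        fps=seq.fps,
        participant_id=seq.participant_id,
        speed_class=seq.speed_class,
        speed_kmh=seq.speed_kmh,
    )
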