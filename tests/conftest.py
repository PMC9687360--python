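"""Shared fixtures and independent pixel-counting oracles.

The oracle implementations here are deliberately naive (nested Python
loops, explicit run detection) and share no code with the package; they
define ground truth for the feature-extraction tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitspeed.features import DegenerateFrameError


@pytest.fixture
def pi_walker() -> np.ndarray:
    """The Π-shaped walker: 60x30 torso atop two 10-col legs (rows 60-99).

    Closed-form features: H=100, W1=W2=W3=30, apparent area
    60*30 + 2*40*10 = 2600, box area 3000, inter-leg area 40*10 = 400,
    hence hw1=hw2=hw3=10/3, a1=13/15, a2=2/15 and a1+a2=1.
    """
    mask = np.zeros((100, 30), dtype=bool)
    mask[0:60, :] = True  # torso
    mask[60:100, 0:10] = True  # left leg
    mask[60:100, 20:30] = True  # right leg
    return mask


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_bbox(mask):
    """Scan every pixel for the tight bounding box: (top, left, height, width)."""
    rows, cols = [], []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                rows.append(r)
                cols.append(c)
    if not rows:
        raise DegenerateFrameError("empty mask (oracle)")
    return min(rows), min(cols), max(rows) - min(rows) + 1, max(cols) - min(cols) + 1


def oracle_band_rows(top, height, band):
    lo, hi = band
    r0 = top + int(np.floor(lo * height))
    r1 = top + int(np.floor(hi * height))
    return r0, max(r1, r0 + 1)


def oracle_band_width(mask, top, height, band):
    r0, r1 = oracle_band_rows(top, height, band)
    best = 0
    for r in range(r0, min(r1, mask.shape[0])):
        cc = [c for c in range(mask.shape[1]) if mask[r, c]]
        if cc:
            best = max(best, cc[-1] - cc[0] + 1)
    if best == 0:
        raise DegenerateFrameError("empty band (oracle)")
    return best


def oracle_inter_leg_area(mask, top, height, band):
    r0, r1 = oracle_band_rows(top, height, band)
    total = 0
    for r in range(r0, min(r1, mask.shape[0])):
        runs = []
        in_run = False
        for c in range(mask.shape[1]):
            if mask[r, c] and not in_run:
                runs.append([c, c])
                in_run = True
            elif mask[r, c]:
                runs[-1][1] = c
            else:
                in_run = False
        if len(runs) >= 2:
            span = runs[-1][0] - runs[0][1] - 1
            fg_between = sum(
                1 for c in range(runs[0][1] + 1, runs[-1][0]) if mask[r, c]
            )
            total += span - fg_between
    return total


def oracle_frame_features(
    mask, mid_band=(1 / 3, 2 / 3), low_band=(2 / 3, 1.0), a2_band=(0.0, 1.0)
):
    """Fully independent recomputation of the five ratios."""
    top, left, h, w1 = oracle_bbox(mask)
    w2 = oracle_band_width(mask, top, h, mid_band)
    w3 = oracle_band_width(mask, top, h, low_band)
    fg = sum(
        1
        for r in range(top, top + h)
        for c in range(left, left + w1)
        if mask[r, c]
    )
    between = oracle_inter_leg_area(mask, top, h, a2_band)
    return np.array([h / w1, h / w2, h / w3, fg / (h * w1), between / (h * w1)])


def random_blob_mask(rng: np.random.Generator, max_side: int = 64) -> np.ndarray:
    """A random test mask: either pure salt noise or a crude two-legged figure."""
    h = int(rng.integers(8, max_side + 1))
    w = int(rng.integers(8, max_side + 1))
    if rng.random() < 0.5:
        mask = rng.random((h, w)) < rng.uniform(0.15, 0.6)
        if not mask.any():
            mask[h // 2, w // 2] = True
        return mask
    mask = np.zeros((h, w), dtype=bool)
    torso_h = max(1, int(0.6 * h))
    t_left, t_right = w // 4, max(w // 4 + 1, 3 * w // 4)
    mask[:torso_h, t_left:t_right] = True
    leg_w = max(1, (t_right - t_left) // 3)
    mask[torso_h:, t_left : t_left + leg_w] = True
    mask[torso_h:, t_right - leg_w : t_right] = True
    return mask
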