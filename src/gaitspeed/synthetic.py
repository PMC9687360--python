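"""Synthetic treadmill-gait generators.

Real studies of silhouette-based speed classification use licensed video
datasets (lateral view, treadmill, 60 fps, VGA). This module generates
stand-in data with the same statistical structure at two levels:

* **Silhouette level** — an articulated stick-figure walker (head disc,
  torso rectangle, two rigid legs swinging in antiphase) rasterized to
  binary VGA frames. The leg angle follows
  ``theta(t) = A * sin(2*pi*cadence*t)``, so the inter-leg aperture — and
  with it the width- and area-based measurements — oscillates at twice the
  cadence, the classic quasi-periodic gait signature.
* **Signal level** — the five ratio signals drawn directly from a latent
  oscillator model, orders of magnitude faster, with a configurable
  correlation structure between features. This is the default input for
  classifier experiments.

Both levels are deterministic given their seed. Cadence and stride
amplitude increase linearly with treadmill speed, so the three speed
classes differ in dominant frequency and oscillation amplitude, and
per-participant random effects (body scale, cadence offset, feature
offsets) make participant-grouped cross-validation meaningful.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from skimage.draw import disk, polygon

from .core import (
    FEATURE_NAMES,
    FeatureSignalSet,
    SilhouetteSequence,
    SpeedClass,
    speed_class_of,
)

__all__ = [
    "WalkerParams",
    "CohortSpec",
    "SignalConfig",
    "ConfigurationError",
    "simulate_walker_sequence",
    "simulate_cohort",
    "simulate_signal_set",
    "simulate_signal_cohort",
]

#: Representative treadmill speed (km/h) for each class (its band midpoint).
CLASS_SPEED_KMH: dict[SpeedClass, float] = {
    SpeedClass.SLOW: 2.5,
    SpeedClass.NORMAL: 4.5,
    SpeedClass.FAST: 6.5,
}


class ConfigurationError(ValueError):
    """Raised when generator parameters are geometrically impossible."""


@dataclass(frozen=True)
class WalkerParams:
    """Geometry and dynamics of the articulated walker.

    Lengths are fractions of the body height; the walker is rasterized on a
    VGA canvas (480 x 640), vertically centred, with no horizontal
    translation (treadmill walking). Cadence (steps/s) and stride-angle
    amplitude (rad) grow linearly with treadmill speed:

        cadence_hz(v) = cadence_base + cadence_slope * (v - 2)
        stride_angle_amplitude(v) = stride_base + stride_slope * (v - 2)

    Arms are omitted by default: in a lateral silhouette the torso largely
    occludes arm swing, and a clean mid-body band keeps the width
    measurements well defined.
    """

    body_height_px: int = 360
    torso_width_frac: float = 0.16
    leg_length_frac: float = 0.50
    head_radius_frac: float = 0.07
    leg_width_frac: float = 0.45  # fraction of torso width, per leg
    cadence_base: float = 0.9
    cadence_slope: float = 0.25
    stride_base: float = 0.25
    stride_slope: float = 0.05
    participant_scale: float = 1.0
    cadence_offset: float = 0.0
    noise_sd: float = 0.0
    canvas_shape: tuple[int, int] = (480, 640)
    include_arms: bool = False

    def __post_init__(self) -> None:
        if self.body_height_px <= 0:
            raise ValueError("body_height_px must be positive")
        for name in ("torso_width_frac", "leg_length_frac", "head_radius_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.participant_scale <= 0:
            raise ValueError("participant_scale must be positive")
        for v in (2.0, 7.0):
            amp = self.stride_angle_amplitude(v)
            if not 0.0 <= amp < math.pi / 2:
                raise ValueError(f"stride amplitude at {v} km/h out of [0, pi/2): {amp}")
        if self.cadence_hz(7.0) <= self.cadence_hz(2.0) and self.cadence_slope != 0:
            raise ValueError("cadence must be non-decreasing in speed")

    def cadence_hz(self, speed_kmh: float) -> float:
        """Steps per second at a given treadmill speed, with participant offset."""
        return self.cadence_base + self.cadence_slope * (speed_kmh - 2.0) + self.cadence_offset

    def stride_angle_amplitude(self, speed_kmh: float) -> float:
        """Peak leg angle from vertical (rad) at a given treadmill speed."""
        return self.stride_base + self.stride_slope * (speed_kmh - 2.0)


@dataclass(frozen=True)
class CohortSpec:
    """Layout of a synthetic cohort: participants x speeds x repeats.

    The defaults mirror a 34-participant treadmill protocol: speeds 2-7 km/h
    in 1 km/h steps, two sequences per speed (12 per participant, 408 in
    total), at least 240 frames each at 60 fps.
    """

    n_participants: int = 34
    speeds_kmh: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
    sequences_per_speed: int = 2
    min_frames: int = 240
    fps: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.sequences_per_speed < 1 or self.min_frames < 1:
            raise ValueError("cohort counts must be positive")
        for v in self.speeds_kmh:
            speed_class_of(v)  # validates the 2-7 km/h range

    @property
    def n_sequences(self) -> int:
        return self.n_participants * len(self.speeds_kmh) * self.sequences_per_speed

    def participant_ids(self) -> list[str]:
        return [f"P{i:02d}" for i in range(self.n_participants)]


# ---------------------------------------------------------------------------
# silhouette level
# ---------------------------------------------------------------------------


def _render_walker_frame(
    params: WalkerParams,
    theta: float,
    jitter_rc: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rasterize one pose (leg angle ``theta`` from vertical) to a boolean mask."""
    rows, cols = params.canvas_shape
    h = params.body_height_px * params.participant_scale
    if h > rows - 4:
        raise ConfigurationError(
            f"walker height {h:.0f}px does not fit the {rows}px canvas"
        )
    top = (rows - h) / 2.0 + jitter_rc[0]
    cx = cols / 2.0 + jitter_rc[1]
    r_head = params.head_radius_frac * h
    torso_w = params.torso_width_frac * h
    leg_len = params.leg_length_frac * h
    leg_w = params.leg_width_frac * torso_w
    hip_row = top + h - leg_len

    mask = np.zeros((rows, cols), dtype=bool)
    # head
    rr, cc = disk((top + r_head, cx), r_head, shape=(rows, cols))
    mask[rr, cc] = True
    # torso (slight overlap with the head so the silhouette is connected)
    t0, t1 = top + 1.6 * r_head, hip_row
    rr, cc = polygon(
        [t0, t0, t1, t1],
        [cx - torso_w / 2, cx + torso_w / 2, cx + torso_w / 2, cx - torso_w / 2],
        shape=(rows, cols),
    )
    mask[rr, cc] = True
    # two rigid legs in antiphase: angles +theta and -theta from vertical
    for sign in (+1.0, -1.0):
        ang = sign * theta
        dr, dc = leg_len * math.cos(ang), leg_len * math.sin(ang)
        # perpendicular half-width vector
        pr, pc = -math.sin(ang) * leg_w / 2, math.cos(ang) * leg_w / 2
        rr, cc = polygon(
            [hip_row - pr, hip_row + pr, hip_row + dr + pr, hip_row + dr - pr],
            [cx - pc, cx + pc, cx + dc + pc, cx + dc - pc],
            shape=(rows, cols),
        )
        mask[rr, cc] = True
    if params.include_arms:
        arm_len = 0.75 * leg_len
        arm_w = 0.5 * leg_w
        shoulder = top + 2.2 * r_head
        for sign in (+1.0, -1.0):
            ang = -0.6 * sign * theta  # arms counter-swing the legs
            dr, dc = arm_len * math.cos(ang), arm_len * math.sin(ang)
            pr, pc = -math.sin(ang) * arm_w / 2, math.cos(ang) * arm_w / 2
            rr, cc = polygon(
                [shoulder - pr, shoulder + pr, shoulder + dr + pr, shoulder + dr - pr],
                [cx - pc, cx + pc, cx + dc + pc, cx + dc - pc],
                shape=(rows, cols),
            )
            mask[rr, cc] = True
    return mask


def simulate_walker_sequence(
    params: WalkerParams,
    speed_kmh: float,
    n_frames: int,
    fps: float = 60.0,
    seed: int | None = 0,
    participant_id: str = "P00",
    phase: float = 0.0,
) -> SilhouetteSequence:
    """Render a lateral-view walking sequence at a given treadmill speed.

    The leg angle follows ``A * sin(2*pi*f*t + phase)`` with the two legs in
    antiphase, so silhouette width and inter-leg aperture oscillate at twice
    the cadence ``f``. Deterministic given ``seed``.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    speed_class_of(speed_kmh)  # range check
    rng = np.random.default_rng(seed)
    amp = params.stride_angle_amplitude(speed_kmh)
    f = params.cadence_hz(speed_kmh)
    frames = []
    for i in range(n_frames):
        theta = amp * math.sin(2.0 * math.pi * f * i / fps + phase)
        jitter = (
            tuple(rng.normal(0.0, params.noise_sd, size=2))
            if params.noise_sd > 0
            else (0.0, 0.0)
        )
        frames.append(_render_walker_frame(params, theta, jitter))
    return SilhouetteSequence(
        frames=frames, fps=fps, participant_id=participant_id, speed_kmh=speed_kmh
    )


def simulate_cohort(
    spec: CohortSpec, params: WalkerParams | None = None
) -> Iterator[SilhouetteSequence]:
    """Yield the full cohort of silhouette sequences, lazily (they are large).

    Per-participant random effects — a log-normal body-scale factor
    (sd 0.05) and a Gaussian cadence offset (sd 0.05 Hz) — are drawn once
    per participant from the cohort seed, then every sequence gets its own
    random initial gait phase and render seed.
    """
    params = params or WalkerParams()
    root = np.random.SeedSequence(spec.seed)
    effects_rng = np.random.default_rng(root.spawn(1)[0])
    seq_seeds = iter(root.spawn(spec.n_sequences))
    for pid in spec.participant_ids():
        scale = params.participant_scale * float(np.exp(effects_rng.normal(0.0, 0.05)))
        cad_off = float(effects_rng.normal(0.0, 0.05))
        p_params = dataclasses.replace(params, participant_scale=scale, cadence_offset=cad_off)
        for speed in spec.speeds_kmh:
            for _ in range(spec.sequences_per_speed):
                ss = next(seq_seeds)
                phase = float(np.random.default_rng(ss).uniform(0.0, 2.0 * math.pi))
                yield simulate_walker_sequence(
                    p_params,
                    speed,
                    n_frames=spec.min_frames,
                    fps=spec.fps,
                    seed=ss,
                    participant_id=pid,
                    phase=phase,
                )


# ---------------------------------------------------------------------------
# signal level
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalConfig:
    """Latent-oscillator model of the five ratio signals.

    Latent channels come in two kinds: sinusoids at an integer harmonic of
    twice the cadence (the aperture frequency) with a fixed phase, and —
    optionally — shared unit-variance white-noise channels. A feature is a
    mean plus a loading-weighted sum of channels plus its own white noise:

        x_j(t) = mean_j + shift_class_j + offset_j
                 + amp_class * sum_k L[j,k] * sin(2*pi*m_k*(2*f)*t + phi_k + phi0)
                 + sum_q L[j, K+q] * n_q(t) + noise_sd_j * eps

    Sinusoid channels at the same harmonic but phases 90 degrees apart — or
    at different harmonics — are orthogonal over whole cycles, so the
    loadings matrix sets the between-feature correlation structure directly;
    shared noise channels let two features be near-duplicates without making
    either individually clean. The default configuration reproduces the
    qualitative pattern seen in real treadmill silhouettes: a strongly
    inter-correlated block (HW1, HW3, A1), with HW2 and A2 only weakly
    correlated with everything.
    """

    channels: tuple[tuple[int, float], ...] = ((1, 0.0), (1, math.pi / 2))
    noise_channels: int = 0
    loadings: tuple[tuple[float, ...], ...] = (
        (0.28, 0.0),  # HW1: main quadrature
        (0.13, 0.13),  # HW2: mixed, noise-dominated -> weak with everything
        (0.33, 0.0),  # HW3: main quadrature (correlated with HW1, A1)
        (0.040, 0.0),  # A1: main quadrature, small scale
        (0.0, 0.030),  # A2: orthogonal quadrature
    )
    means: tuple[float, ...] = (2.60, 3.10, 3.30, 0.86, 0.055)
    noise_sd: tuple[float, ...] = (0.10, 0.18, 0.11, 0.012, 0.010)
    class_amp: tuple[float, float, float] = (0.80, 1.00, 1.25)  # slow, normal, fast
    class_mean_shift: tuple[tuple[float, ...], ...] = (
        (0.15, 0.10, 0.20, 0.010, -0.012),
        (0.0, 0.0, 0.0, 0.0, 0.0),
        (-0.18, -0.12, -0.25, -0.012, 0.015),
    )
    cadence_base: float = 0.9
    cadence_slope: float = 0.25
    participant_sd: tuple[float, ...] = (0.08, 0.08, 0.08, 0.008, 0.004)
    cadence_offset_sd: float = 0.05
    #: per-sequence cadence jitter drawn independently for every sinusoid
    #: channel (Hz); features sharing a channel share its jitter, so
    #: duplicates stay duplicates while independent sources de-synchronize
    channel_jitter_sd: float = 0.0
    #: optional channel-level DC structure: class shifts (3 x K, channel
    #: units) and per-participant channel offset scatter (K,). Features
    #: inherit both through the loadings, so features sharing a channel
    #: share the class cue *and* the participant nuisance — the mechanism
    #: that makes a duplicated feature truly redundant.
    channel_class_shift: tuple[tuple[float, ...], ...] | None = None
    channel_participant_sd: tuple[float, ...] | None = None
    #: like channel_participant_sd but redrawn for every sequence — a
    #: measurement-level nuisance rather than an identity-level one
    channel_sequence_sd: tuple[float, ...] | None = None

    def cadence_hz(self, speed_kmh: float) -> float:
        return self.cadence_base + self.cadence_slope * (speed_kmh - 2.0)

    @classmethod
    def three_source(cls) -> "SignalConfig":
        """A construction with exactly three independent informative sources.

        HW1, HW2 and A2 load on three mutually orthogonal sinusoid channels;
        HW3 is a near-duplicate of HW1 and A1 a near-duplicate of HW2
        (duplicate pairs share their sinusoid *and* their noise channel, so
        their pairwise R² is close to 1 while no single channel is clean).
        The class information lives in channel-level DC shifts masked by
        per-sequence channel offsets of comparable size: one feature
        alone is ambiguous, but the three independent sources average the
        nuisance away, so a source-covering triple is markedly more
        accurate than any single feature while a duplicated feature adds
        (almost) no information. Cadence is deliberately speed-independent
        here so the mean cue is the only class signal. Any subset covering
        the three sources while avoiding a duplicate pair is weakly
        correlated and discriminative — the ground truth for redundancy
        experiments.
        """
        return cls(
            channels=((1, 0.0), (1, math.pi / 2), (2, 0.0)),
            noise_channels=3,
            loadings=(
                # sinusoids s1,s2,s3 | shared noise n1,n2,n3
                (0.20, 0.0, 0.0, 0.30, 0.0, 0.0),  # HW1 <- s1 + n1
                (0.0, 0.12, 0.0, 0.0, 0.20, 0.0),  # HW2 <- s2 + n2
                (0.19, 0.0, 0.0, 0.285, 0.0, 0.0),  # HW3 ~ HW1 (shares s1 and n1)
                (0.0, 0.030, 0.0, 0.0, 0.050, 0.0),  # A1 ~ HW2 (shares s2 and n2)
                (0.0, 0.0, 0.020, 0.0, 0.0, 0.035),  # A2 <- s3 + n3
            ),
            noise_sd=(0.02, 0.015, 0.0, 0.0, 0.004),
            class_mean_shift=tuple((0.0,) * 5 for _ in range(3)),
            class_amp=(1.0, 1.0, 1.0),
            cadence_base=1.2,
            cadence_slope=0.0,
            cadence_offset_sd=0.05,
            channel_jitter_sd=0.08,
            participant_sd=(0.01, 0.01, 0.0, 0.0, 0.002),
            channel_class_shift=(
                (-2.6, -2.6, -2.6, 0.0, 0.0, 0.0),
                (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
                (2.6, 2.6, 2.6, 0.0, 0.0, 0.0),
            ),
            channel_sequence_sd=(1.0, 1.0, 1.0, 0.0, 0.0, 0.0),
        )

    @classmethod
    def separable(cls) -> "SignalConfig":
        """Widely separated class means and low noise: a near-noiseless ceiling case."""
        return cls(
            class_mean_shift=(
                (1.0, 1.0, 1.0, 0.10, -0.04),
                (0.0, 0.0, 0.0, 0.0, 0.0),
                (-1.0, -1.0, -1.0, -0.10, 0.04),
            ),
            noise_sd=(0.02, 0.02, 0.02, 0.004, 0.003),
            participant_sd=(0.01, 0.01, 0.01, 0.001, 0.001),
        )


def simulate_signal_set(
    speed_class: SpeedClass | str,
    n_frames: int,
    participant_effect: np.ndarray | None = None,
    seed: int | None = 0,
    config: SignalConfig | None = None,
    fps: float = 60.0,
    cadence_offset: float = 0.0,
    participant_id: str = "P00",
    speed_kmh: float | None = None,
    channel_offsets: np.ndarray | None = None,
) -> FeatureSignalSet:
    """Draw the five ratio signals for one sequence from the latent model."""
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    try:
        speed_class = SpeedClass(speed_class)
    except ValueError as exc:
        raise ValueError(f"unknown speed class: {speed_class!r}") from exc
    config = config or SignalConfig()
    speed = CLASS_SPEED_KMH[speed_class] if speed_kmh is None else speed_kmh
    class_idx = {SpeedClass.SLOW: 0, SpeedClass.NORMAL: 1, SpeedClass.FAST: 2}[speed_class]

    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * math.pi)
    t = np.arange(n_frames) / fps
    jitter = (
        rng.normal(0.0, config.channel_jitter_sd, size=len(config.channels))
        if config.channel_jitter_sd > 0
        else np.zeros(len(config.channels))
    )
    chans = np.stack(
        [
            np.sin(
                2.0
                * math.pi
                * m
                * 2.0
                * (config.cadence_hz(speed) + cadence_offset + jit)
                * t
                + phi
                + m * phi0
            )
            for (m, phi), jit in zip(config.channels, jitter)
        ]
    )  # (K, T)
    loadings = np.asarray(config.loadings, dtype=float)
    k_sin = len(config.channels)
    if loadings.shape != (len(FEATURE_NAMES), k_sin + config.noise_channels):
        raise ValueError(
            f"loadings must be 5 x {k_sin + config.noise_channels}, got {loadings.shape}"
        )
    means = np.asarray(config.means, dtype=float)
    shift = np.asarray(config.class_mean_shift[class_idx], dtype=float)
    offset = np.zeros(5) if participant_effect is None else np.asarray(participant_effect, float)
    noise_sd = np.asarray(config.noise_sd, dtype=float)
    signals = (
        (means + shift + offset)[:, None]
        + config.class_amp[class_idx] * loadings[:, :k_sin] @ chans
        + noise_sd[:, None] * rng.standard_normal((len(FEATURE_NAMES), n_frames))
    )
    if config.noise_channels:
        shared = rng.standard_normal((config.noise_channels, n_frames))
        signals += loadings[:, k_sin:] @ shared
    # channel-level DC: class shift plus participant/sequence offsets,
    # propagated into the features through the loadings
    dc = np.zeros(loadings.shape[1])
    if config.channel_class_shift is not None:
        dc += np.asarray(config.channel_class_shift[class_idx], dtype=float)
    if channel_offsets is not None:
        dc += np.asarray(channel_offsets, dtype=float)
    if config.channel_sequence_sd is not None:
        dc += rng.normal(0.0, np.asarray(config.channel_sequence_sd, dtype=float))
    if dc.any():
        signals += (loadings @ dc)[:, None]
    return FeatureSignalSet(
        signals=signals,
        fps=fps,
        participant_id=participant_id,
        speed_class=speed_class,
        speed_kmh=speed,
    )


def simulate_signal_cohort(
    spec: CohortSpec, config: SignalConfig | None = None
) -> list[FeatureSignalSet]:
    """Generate ratio signals for the full cohort directly (no rasterization).

    Participant random effects (per-feature offsets, cadence offset) are
    drawn once per participant; every sequence then gets an independent
    seed, so the whole cohort is deterministic given ``spec.seed``.
    """
    config = config or SignalConfig()
    root = np.random.SeedSequence(spec.seed)
    effects_rng = np.random.default_rng(root.spawn(1)[0])
    seq_seeds = iter(root.spawn(spec.n_sequences))
    out: list[FeatureSignalSet] = []
    for pid in spec.participant_ids():
        offsets = effects_rng.normal(0.0, np.asarray(config.participant_sd, float))
        cad_off = float(effects_rng.normal(0.0, config.cadence_offset_sd))
        chan_off = (
            effects_rng.normal(0.0, np.asarray(config.channel_participant_sd, float))
            if config.channel_participant_sd is not None
            else None
        )
        for speed in spec.speeds_kmh:
            for _ in range(spec.sequences_per_speed):
                out.append(
                    simulate_signal_set(
                        speed_class_of(speed),
                        n_frames=spec.min_frames,
                        participant_effect=offsets,
                        seed=next(seq_seeds),
                        config=config,
                        fps=spec.fps,
                        cadence_offset=cad_off,
                        participant_id=pid,
                        speed_kmh=speed,
                        channel_offsets=chan_off,
                    )
                )
    return out
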