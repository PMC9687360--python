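"""Walker renderer and signal generators: determinism, periodicity, cohort layout."""

import dataclasses
import math

import numpy as np
import pytest

from gaitspeed.core import SpeedClass, speed_class_of
from gaitspeed.correlation import r_squared
from gaitspeed.features import extract_frame_features, extract_sequence_features
from gaitspeed.synthetic import (
    CLASS_SPEED_KMH,
    CohortSpec,
    ConfigurationError,
    SignalConfig,
    WalkerParams,
    simulate_cohort,
    simulate_signal_cohort,
    simulate_signal_set,
    simulate_walker_sequence,
)

SMALL = WalkerParams(body_height_px=120)


def test_speed_class_bucketing():
    assert speed_class_of(2.0) is SpeedClass.SLOW
    assert speed_class_of(3.0) is SpeedClass.SLOW
    assert speed_class_of(4.0) is SpeedClass.NORMAL
    assert speed_class_of(5.0) is SpeedClass.NORMAL
    assert speed_class_of(6.0) is SpeedClass.FAST
    assert speed_class_of(7.0) is SpeedClass.FAST
    with pytest.raises(ValueError):
        speed_class_of(1.0)


class TestWalkerSequence:
    def test_zero_amplitude_freezes_the_walker(self):
        params = dataclasses.replace(SMALL, stride_base=0.0, stride_slope=0.0)
        seq = simulate_walker_sequence(params, 5.0, n_frames=8, seed=0)
        for frame in seq.frames[1:]:
            np.testing.assert_array_equal(frame, seq.frames[0])
        fs = extract_sequence_features(seq)
        assert np.ptp(fs.signals, axis=1).max() == 0.0

    def test_same_seed_bit_identical(self):
        a = simulate_walker_sequence(SMALL, 3.0, n_frames=5, seed=11)
        b = simulate_walker_sequence(SMALL, 3.0, n_frames=5, seed=11)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa, fb)

    def test_every_frame_has_foreground(self):
        seq = simulate_walker_sequence(SMALL, 7.0, n_frames=20, seed=2)
        assert all(f.any() for f in seq.frames)
        assert seq.speed_class is SpeedClass.FAST

    def test_aperture_oscillates_at_twice_cadence(self):
        """Dominant A2 frequency equals 2 x cadence, within one FFT bin.

        Oracle: the leg aperture is proportional to |sin(2*pi*f*t)|, whose
        spectrum peaks at 2f; for cadence 1.8 Hz that is 3.6 Hz, and with
        240 frames at 60 fps the bin width is 0.25 Hz.
        """
        params = WalkerParams(
            cadence_base=1.8, cadence_slope=0.0, stride_base=0.35, stride_slope=0.0
        )
        seq = simulate_walker_sequence(params, 4.0, n_frames=240, fps=60.0, seed=3)
        a2 = extract_sequence_features(seq).signal("A2")
        a2 = a2 - a2.mean()
        freqs = np.fft.rfftfreq(240, d=1 / 60.0)
        peak = freqs[np.abs(np.fft.rfft(a2)).argmax()]
        assert abs(peak - 3.6) <= 0.25

    def test_scale_invariance_of_ratios(self):
        """Doubling the body scale changes pixels but not ratios (<= 2% rel.).

        Tested at the native body height (360 px) on an enlarged canvas so
        the doubled walker still fits; limb widths below ~25 px quantize
        worse than 2% and are out of the stated rasterization regime.
        """
        base = WalkerParams(body_height_px=360, canvas_shape=(1600, 900))
        for phase_frac in (0.0, 0.2, 0.3, 0.6, 0.8):
            small = simulate_walker_sequence(
                base, 6.0, n_frames=1, seed=0, phase=2 * math.pi * phase_frac
            )
            big = simulate_walker_sequence(
                dataclasses.replace(base, participant_scale=2.0),
                6.0,
                n_frames=1,
                seed=0,
                phase=2 * math.pi * phase_frac,
            )
            fa = extract_frame_features(small.frames[0]).as_array()
            fb = extract_frame_features(big.frames[0]).as_array()
            rel = np.abs(fb - fa) / np.abs(fa).clip(1e-9)
            assert rel[:4].max() <= 0.02  # HW1-3, A1
            # A2 can be 0 at closed-leg phases; compare absolutely there
            assert abs(fb[4] - fa[4]) <= 0.02 * max(fa[4], 0.25)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_walker_sequence(SMALL, 4.0, n_frames=0)
        with pytest.raises(ValueError):
            simulate_walker_sequence(SMALL, 9.0, n_frames=5)
        with pytest.raises(ConfigurationError):
            simulate_walker_sequence(
                WalkerParams(body_height_px=600), 4.0, n_frames=1
            )


class TestSilhouetteCohort:
    def test_small_cohort_counts_and_balance(self):
        spec = CohortSpec(n_participants=2, min_frames=4, seed=5)
        seqs = list(simulate_cohort(spec, SMALL))
        assert len(seqs) == 2 * 6 * 2 == 24
        per_class = {c: 0 for c in SpeedClass}
        for s in seqs:
            per_class[s.speed_class] += 1
            assert len(s.frames) >= spec.min_frames
        assert set(per_class.values()) == {8}

    def test_participant_effects_deterministic(self):
        spec = CohortSpec(n_participants=2, speeds_kmh=(2.0,), sequences_per_speed=1,
                          min_frames=2, seed=9)
        a = [s.frames[0] for s in simulate_cohort(spec, SMALL)]
        b = [s.frames[0] for s in simulate_cohort(spec, SMALL)]
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)


class TestSignalModel:
    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            simulate_signal_set("sprinting", 10)

    def test_classes_differ_in_dominant_frequency(self):
        cfg = SignalConfig(noise_sd=(0.0,) * 5)
        freqs = {}
        for cls in (SpeedClass.SLOW, SpeedClass.FAST):
            fs = simulate_signal_set(cls, 240, seed=1, config=cfg)
            x = fs.signal("HW1") - fs.signal("HW1").mean()
            fgrid = np.fft.rfftfreq(240, d=1 / 60.0)
            freqs[cls] = fgrid[np.abs(np.fft.rfft(x)).argmax()]
        expected = {
            cls: 2 * cfg.cadence_hz(CLASS_SPEED_KMH[cls]) for cls in freqs
        }
        for cls in freqs:
            assert abs(freqs[cls] - expected[cls]) <= 0.25
        assert freqs[SpeedClass.FAST] > freqs[SpeedClass.SLOW]

    def test_equal_loadings_zero_noise_gives_r2_one(self):
        cfg = SignalConfig(
            loadings=((0.3, 0.0), (0.15, 0.0), (0.3, 0.0), (0.05, 0.0), (0.02, 0.0)),
            noise_sd=(0.0,) * 5,
        )
        fs = simulate_signal_set(SpeedClass.NORMAL, 240, seed=2, config=cfg)
        assert r_squared(fs.signal("HW1"), fs.signal("HW2")) == pytest.approx(1.0)

    def test_independent_noise_features_have_near_zero_r2(self):
        """Monte-Carlo oracle: mean R^2 of independent white series is tiny."""
        cfg = SignalConfig(
            loadings=tuple((0.0, 0.0) for _ in range(5)),
            noise_sd=(1.0,) * 5,
        )
        vals = []
        for rep in range(100):
            fs = simulate_signal_set(SpeedClass.SLOW, 240, seed=rep, config=cfg)
            vals.append(r_squared(fs.signal("HW1"), fs.signal("A2")))
        assert np.mean(vals) < 0.05

    def test_signal_cohort_default_layout(self):
        spec = CohortSpec(seed=0)
        sets = simulate_signal_cohort(spec)
        assert len(sets) == 34 * 6 * 2 == 408
        counts = {c: 0 for c in SpeedClass}
        for s in sets:
            counts[s.speed_class] += 1
            assert s.n_frames == 240
        assert set(counts.values()) == {136}
        assert len({s.participant_id for s in sets}) == 34

    def test_signal_cohort_deterministic(self):
        spec = CohortSpec(n_participants=3, seed=21)
        a = simulate_signal_cohort(spec)
        b = simulate_signal_cohort(spec)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.signals, sb.signals)
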