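"""f0 tracking, loudness, formants, spectral tilt, profile extraction."""

import math

import numpy as np
import pytest
from scipy.signal import lfilter

from prosodiff import (
    AnalysisConfig,
    AudioSignal,
    extract_profile,
    peak_normalise,
)
from prosodiff.prosody_features import (
    F0Track,
    estimate_formants,
    f0_statistics,
    harmonic_amplitudes,
    loudness_stats,
    spectral_tilt_stats,
    track_f0,
)
from prosodiff.segmentation import SegmentTrack, detect_pauses
from prosodiff.synthetic_voice import (
    UtteranceSpec,
    build_reading_spec,
    synthesize_utterance,
    tilt_filter_coefficient,
    _tilt_filter_apply,
)
from conftest import RATE, make_glide, make_noise, make_sine


def pulse_train(f0: float, duration_s: float = 2.0, rate: float = RATE,
                smooth: float = 0.95) -> AudioSignal:
    n = int(duration_s * rate)
    src = np.zeros(n)
    src[:: int(round(rate / f0))] = 1.0
    x = lfilter([1.0], [1.0, -smooth], src)
    return AudioSignal(x / np.max(np.abs(x)), rate)


def full_speech_track(sig: AudioSignal) -> SegmentTrack:
    return SegmentTrack(
        intervals=((0.0, sig.duration, "speech"),), total_duration=sig.duration
    )


class TestTrackF0:
    def test_constant_pulse_train_within_1_hz(self):
        track = track_f0(pulse_train(200.0))
        assert track.n_voiced > 100
        assert np.all(np.abs(track.voiced_f0 - 200.0) <= 1.0)

    def test_white_noise_has_no_voiced_frames(self):
        sig = AudioSignal(make_noise(2.0), RATE)
        track = track_f0(sig)
        assert track.n_voiced == 0

    def test_linear_glide_tracked_within_3_hz(self):
        sig = make_glide(150.0, 250.0, duration_s=2.0)
        track = track_f0(sig)
        times = track.frame_times[track.voiced_mask]
        target = 150.0 + (250.0 - 150.0) * times / 2.0
        assert track.n_voiced > 150
        assert np.max(np.abs(track.voiced_f0 - target)) <= 3.0

    def test_floor_above_ceiling_rejected(self):
        with pytest.raises(ValueError):
            track_f0(pulse_train(200.0), floor_hz=400, ceiling_hz=100)


class TestF0Statistics:
    def _track(self, values):
        values = np.asarray(values, dtype=float)
        return F0Track(
            frame_times=np.arange(values.size) * 0.01,
            f0_hz=values,
            voiced_mask=np.ones(values.size, dtype=bool),
        )

    def test_constant_contour(self):
        stats = f0_statistics(self._track([200.0] * 20))
        assert stats.f0_min_hz == stats.f0_max_hz == stats.f0_level_hz == 200.0
        assert stats.f0_range_st == 0.0
        assert stats.f0_sd_hz == 0.0

    def test_three_point_contour_arithmetic(self):
        """{180, 200, 220} Hz: level 200, population sd 20*sqrt(2/3)."""
        stats = f0_statistics(self._track([180.0, 200.0, 220.0] * 4))
        assert stats.f0_level_hz == pytest.approx(200.0)
        assert stats.f0_sd_hz == pytest.approx(20.0 * math.sqrt(2.0 / 3.0), abs=1e-9)
        assert stats.f0_range_st == pytest.approx(12 * math.log2(220 / 180))

    def test_glide_range_closed_form(self):
        """150->250 Hz glide: range = 12*log2(250/150) ~ 8.84 st."""
        track = track_f0(make_glide(150.0, 250.0))
        stats = f0_statistics(track)
        assert stats.f0_range_st == pytest.approx(12 * math.log2(250 / 150), abs=0.5)

    def test_too_few_voiced_frames_undefined(self):
        stats = f0_statistics(self._track([200.0] * 5), min_voiced_frames=10)
        assert math.isnan(stats.f0_level_hz)
        assert math.isnan(stats.f0_range_st)

    def test_internal_consistency_range_from_extrema(self):
        stats = f0_statistics(self._track(np.linspace(120, 260, 50)))
        expected = 12 * math.log2(stats.f0_max_hz / stats.f0_min_hz)
        assert stats.f0_range_st == pytest.approx(expected, abs=1e-12)


class TestLoudness:
    def test_full_scale_sine_closed_form(self):
        """RMS of a full-scale sine is 1/sqrt(2) -> -3.01 dB re FS."""
        sig = make_sine(200.0, 1.0, duration_s=1.0)
        stats = loudness_stats(sig, full_speech_track(sig))
        assert stats.rms_level_db == pytest.approx(20 * math.log10(1 / math.sqrt(2)), abs=0.01)
        assert stats.rms_sd_db == pytest.approx(0.0, abs=0.01)

    def test_gain_law_exact(self):
        sig = make_sine(200.0, 1.0)
        half = sig.scaled(0.5)
        a = loudness_stats(sig, full_speech_track(sig))
        b = loudness_stats(half, full_speech_track(half))
        assert a.rms_level_db - b.rms_level_db == pytest.approx(
            20 * math.log10(2.0), abs=1e-9
        )
        assert a.rms_sd_db == pytest.approx(b.rms_sd_db, abs=1e-9)

    def test_amplitude_blocks_show_6_db_and_spread(self):
        t = np.arange(int(2.0 * RATE)) / RATE
        amp = np.where((t // 0.5).astype(int) % 2 == 0, 1.0, 0.5)
        sig = AudioSignal(amp * np.sin(2 * np.pi * 200 * t), RATE)
        stats = loudness_stats(sig, full_speech_track(sig))
        assert stats.rms_sd_db > 1.0
        # mean sits between the two block levels
        assert -9.1 < stats.rms_level_db < -3.0

    def test_no_speech_undefined(self):
        sig = make_sine(200.0, 1.0)
        track = SegmentTrack(
            intervals=((0.0, sig.duration, "pause"),), total_duration=sig.duration
        )
        stats = loudness_stats(sig, track)
        assert math.isnan(stats.rms_level_db)

    def test_calibration_offset_shifts_level_only(self):
        sig = make_sine(200.0, 1.0)
        a = loudness_stats(sig, full_speech_track(sig))
        b = loudness_stats(sig, full_speech_track(sig), calibration_offset_db=94.0)
        assert b.rms_level_db - a.rms_level_db == pytest.approx(94.0)
        assert b.rms_sd_db == a.rms_sd_db


def steady_vowel(f0: float, formants, rate=RATE, h1_h2_db: float = 0.0):
    spec = UtteranceSpec(
        duration_s=2.0, sample_rate=rate, f0_level_hz=f0, f0_range_st=0.01,
        h1_h2_db=h1_h2_db, formants_hz=tuple(formants),
        syllable_times=(1.0,), syllable_amps_db=(0.0,), syllable_width_s=1.8,
    )
    sig, truth = synthesize_utterance(spec)
    return peak_normalise(sig), truth


class TestFormants:
    @pytest.mark.parametrize(
        "formants", [(500.0, 1500.0, 2500.0), (300.0, 2300.0, 3000.0)]
    )
    def test_steady_vowel_recovered_within_5_percent(self, formants):
        sig, _ = steady_vowel(130.0, formants)
        stats, _ = estimate_formants(sig, track_f0(sig))
        for got, want in zip((stats.f1_hz, stats.f2_hz, stats.f3_hz), formants):
            assert got == pytest.approx(want, rel=0.05)

    def test_pure_sine_has_no_formants(self):
        sig = make_sine(200.0, 0.9, duration_s=2.0)
        stats, _ = estimate_formants(sig, track_f0(sig))
        assert math.isnan(stats.f1_hz)


class TestHarmonicAmplitudes:
    def test_two_tone_closed_form(self):
        """Amps (1.0, 0.5) at (f0, 2 f0): H1-H2 = 20*log10(2) ~ 6.02 dB."""
        rate = RATE
        t = np.arange(int(0.1 * rate)) / rate
        frame = 1.0 * np.sin(2 * np.pi * 200 * t) + 0.5 * np.sin(2 * np.pi * 400 * t)
        h1, h2, *_ = harmonic_amplitudes(frame, rate, 200.0, ())
        assert h1 - h2 == pytest.approx(20 * math.log10(2.0), abs=0.1)

    def test_equal_amplitudes_give_zero(self):
        rate = RATE
        t = np.arange(int(0.1 * rate)) / rate
        frame = np.sin(2 * np.pi * 200 * t) + np.sin(2 * np.pi * 400 * t)
        h1, h2, *_ = harmonic_amplitudes(frame, rate, 200.0, ())
        assert h1 - h2 == pytest.approx(0.0, abs=0.1)

    def test_frame_too_short_rejected(self):
        with pytest.raises(ValueError, match="4 periods"):
            harmonic_amplitudes(np.zeros(100), RATE, 100.0, ())

    def test_a1_matches_fft_peak_oracle(self):
        """A1 equals a direct FFT peak measurement on the same frame."""
        from prosodiff.synthetic_voice import _resonator_coeffs

        sig = pulse_train(200.0, smooth=0.0)
        x = lfilter(*_resonator_coeffs(500.0, 80.0, RATE), sig.samples)
        frame = x[1600 : 1600 + int(0.1 * RATE)]
        _, _, a1, *_ = harmonic_amplitudes(frame, RATE, 200.0, (500.0,))
        # oracle: FFT of the identical Hann frame, strongest bin near 400/600
        windowed = (frame - frame.mean()) * np.hanning(frame.size)
        mag = np.abs(np.fft.rfft(windowed, 4 * frame.size))
        freqs = np.fft.rfftfreq(4 * frame.size, 1 / RATE)
        cand = []
        for target in (400.0, 600.0):
            sel = (freqs > target - 50) & (freqs < target + 50)
            cand.append(mag[sel].max())
        oracle = 20 * math.log10(max(cand))
        assert a1 == pytest.approx(oracle, abs=0.5)


class TestSpectralTilt:
    def test_programmed_tilt_flat_filter_recovered(self):
        """Source with programmed H1-H2 = +8 dB, no formant filter."""
        rate = RATE
        n = int(2.0 * rate)
        src = np.zeros(n)
        src[:: int(rate / 150)] = 1.0
        kind, a = tilt_filter_coefficient(8.0, 150.0, rate)
        x = _tilt_filter_apply(src, kind, a)
        sig = peak_normalise(AudioSignal(x, rate))
        f0t = track_f0(sig)
        from prosodiff.prosody_features import FormantTrack

        empty = FormantTrack(
            frame_times=f0t.frame_times[f0t.voiced_mask],
            f1_hz=np.full(f0t.n_voiced, np.nan),
            f2_hz=np.full(f0t.n_voiced, np.nan),
            f3_hz=np.full(f0t.n_voiced, np.nan),
        )
        tilt = spectral_tilt_stats(sig, f0t, empty)
        assert tilt.h1_h2_db == pytest.approx(8.0, abs=1.5)

    def test_steady_vowel_variabilities_near_zero(self):
        sig, _ = steady_vowel(130.0, (500.0, 1500.0, 2500.0), h1_h2_db=4.0)
        f0t = track_f0(sig)
        _, ftr = estimate_formants(sig, f0t)
        tilt = spectral_tilt_stats(sig, f0t, ftr)
        for sd in (tilt.h1_h2_sd_db, tilt.h1_a1_sd_db, tilt.h1_a2_sd_db,
                   tilt.h1_a3_sd_db):
            assert sd <= 0.5

    def test_two_block_source_tilt_mean_and_spread(self):
        """Tilt alternating +4 / +12 dB: level ~ 8 dB, sd well above 2."""
        rate = RATE
        n_half = int(1.0 * rate)
        blocks = []
        for target in (4.0, 12.0, 4.0, 12.0):
            src = np.zeros(n_half)
            src[:: int(rate / 150)] = 1.0
            kind, a = tilt_filter_coefficient(target, 150.0, rate)
            block = _tilt_filter_apply(src, kind, a)
            # remove the DC the raw impulse train carries, equalise level
            block = lfilter([1.0, -1.0], [1.0, -0.995], block)
            blocks.append(block / np.std(block))
        sig = peak_normalise(AudioSignal(np.concatenate(blocks), rate))
        f0t = track_f0(sig)
        from prosodiff.prosody_features import FormantTrack

        empty = FormantTrack(
            frame_times=f0t.frame_times[f0t.voiced_mask],
            f1_hz=np.full(f0t.n_voiced, np.nan),
            f2_hz=np.full(f0t.n_voiced, np.nan),
            f3_hz=np.full(f0t.n_voiced, np.nan),
        )
        tilt = spectral_tilt_stats(sig, f0t, empty)
        assert tilt.h1_h2_db == pytest.approx(8.0, abs=1.5)
        assert tilt.h1_h2_sd_db > 2.0


class TestExtractProfile:
    def test_reading_recovery_within_tolerances(self):
        """End-to-end profile on a programmed reading-like utterance."""
        rng = np.random.default_rng(42)
        spec = build_reading_spec(
            duration_s=8.0, rng=rng, sample_rate=RATE, f0_level_hz=120.0,
            f0_range_st=7.0, h1_h2_db=3.0, formants_hz=(500.0, 1500.0, 2500.0),
            n_pauses=2,
        )
        sig, truth = synthesize_utterance(spec)
        profile = extract_profile(peak_normalise(sig)).to_dict()
        assert profile["f0_level_hz"] == pytest.approx(truth.f0_level_hz, rel=0.02)
        assert profile["f0_range_st"] == pytest.approx(truth.f0_range_st, abs=0.5)
        assert profile["h1_h2_db"] == pytest.approx(truth.h1_h2_db, abs=1.5)
        assert profile["n_pauses"] == truth.n_pauses
        assert profile["mean_pause_s"] == pytest.approx(truth.mean_pause_s, abs=0.02)
        assert profile["speaking_rate_sps"] == pytest.approx(
            truth.n_syllables / truth.speech_span_s, rel=0.06
        )
        for key, want in (("f1_hz", 500.0), ("f2_hz", 1500.0), ("f3_hz", 2500.0)):
            assert profile[key] == pytest.approx(want, rel=0.05)

    def test_deterministic_on_identical_input(self):
        sig, _ = steady_vowel(130.0, (500.0, 1500.0, 2500.0))
        a = extract_profile(sig).to_dict()
        b = extract_profile(sig).to_dict()
        assert a == b

    def test_short_clip_yields_undefined_markers(self):
        sig = AudioSignal(make_noise(0.2), RATE)
        profile = extract_profile(sig)
        assert math.isnan(profile.f0.f0_level_hz)
        assert profile.warnings

    def test_gain_invariance_of_relative_features(self):
        sig, _ = steady_vowel(130.0, (500.0, 1500.0, 2500.0), h1_h2_db=4.0)
        loud = extract_profile(sig).to_dict()
        soft = extract_profile(sig.scaled(0.25)).to_dict()
        for key in ("f0_level_hz", "f0_range_st", "h1_h2_db", "h1_a1_db",
                    "f1_hz", "f2_hz", "f3_hz", "rms_sd_db", "speaking_rate_sps"):
            assert soft[key] == pytest.approx(loud[key], rel=1e-6, abs=1e-6), key
        assert soft["rms_level_db"] - loud["rms_level_db"] == pytest.approx(
            20 * math.log10(0.25), abs=1e-6
        )

    def test_prepended_silence_leaves_profile_unchanged(self):
        """Only leading-silence handling may differ: the pad becomes a
        lead pause, which shifts the speech-interval edge by at most one
        analysis window; all voiced-frame measures stay put."""
        sig, _ = steady_vowel(130.0, (500.0, 1500.0, 2500.0))
        padded = AudioSignal(
            np.concatenate([np.zeros(int(0.5 * RATE)), sig.samples]), RATE
        )
        a = extract_profile(sig).to_dict()
        b = extract_profile(padded).to_dict()
        assert b["n_pauses"] == a["n_pauses"]
        for key in ("f0_level_hz", "f0_range_st", "h1_h2_db", "h1_a2_db",
                    "f1_hz", "f2_hz", "f3_hz"):
            assert b[key] == pytest.approx(a[key], rel=0.01), key
        # loudness may shift by the boundary windows the lead pause absorbs
        assert b["rms_level_db"] == pytest.approx(a["rms_level_db"], abs=0.2)
        assert b["rms_sd_db"] == pytest.approx(a["rms_sd_db"], abs=0.5)
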