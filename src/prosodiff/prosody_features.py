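"""Acoustic-prosodic feature extraction for read speech.

Per reading, the extractor measures the stress-sensitive parameter set:

* fundamental frequency (f0) minimum, maximum, range (semitones),
  standard deviation and level (Hz) from an autocorrelation pitch track;
* number and mean duration of internal silent pauses, and speaking rate
  in syllables per second;
* loudness level and variability as short-window RMS in dB. Absolute
  dB SPL requires a microphone calibration that recordings rarely carry,
  so levels are reported in dB re full scale plus an optional
  user-supplied calibration offset; within-speaker differences are
  unaffected by the offset;
* formant levels F1–F3 (Hz) from LPC root-solving;
* spectral-tilt levels and variabilities H1-H2, H1-A1, H1-A2, H1-A3 (dB),
  where H1/H2 are the amplitudes of the first two harmonics and Ak the
  amplitude of the strongest harmonic near formant Fk. Flatter tilt
  (smaller differences) indicates a tenser, more effortful voice;
  steeper tilt a breathier one.

Undefined quantities are always NaN, never a silent zero. Feature-level
variabilities are population standard deviations over analysis frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.fft import rfft, rfftfreq
from scipy.linalg import solve_toeplitz
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, resample_poly

from .audio_io import AudioSignal
from .segmentation import (
    SegmentTrack,
    PauseStats,
    count_syllable_nuclei,
    detect_pauses,
    pause_stats,
    speaking_rate,
)

__all__ = [
    "AnalysisConfig",
    "F0Track",
    "F0Stats",
    "LoudnessStats",
    "FormantStats",
    "FormantTrack",
    "TiltStats",
    "ProsodyProfile",
    "track_f0",
    "f0_statistics",
    "loudness_stats",
    "estimate_formants",
    "harmonic_amplitudes",
    "spectral_tilt_stats",
    "extract_profile",
    "profiles_to_frame",
    "FEATURE_COLUMNS",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable of the extraction pipeline, with its default.

    f0 bounds default to 60–500 Hz to cover a mixed-gender cohort; the
    voicing threshold 0.45 applies to the normalised autocorrelation
    peak. ``loudness_window_s`` is the 20 ms RMS window; segmentation
    uses its own 30 ms intensity window internally.
    """

    normalise_target: float = 0.99
    silence_threshold_db: float = 25.0
    min_pause_s: float = 0.25
    min_speech_s: float = 0.10
    f0_floor_hz: float = 60.0
    f0_ceiling_hz: float = 500.0
    f0_hop_s: float = 0.010
    voicing_threshold: float = 0.45
    silence_gate_db: float = 35.0
    median_filter_points: int = 5
    robust_f0_extrema: bool = False  # 5th/95th percentiles instead of min/max
    loudness_window_s: float = 0.020
    calibration_offset_db: float = 0.0
    lpc_order: int = 12
    n_formants: int = 3
    formant_rate_hz: float = 10_000.0
    pre_emphasis: float = 0.97
    max_formant_bandwidth_hz: float = 700.0
    formant_freq_range_hz: tuple = (90.0, 4500.0)
    min_voiced_frames: int = 10
    include_pauses_in_rate: bool = True


@dataclass(frozen=True)
class F0Track:
    """Frame-wise fundamental-frequency contour.

    ``f0_hz`` is NaN on unvoiced frames; ``voiced_mask`` marks frames the
    tracker accepted as periodic.
    """

    frame_times: np.ndarray
    f0_hz: np.ndarray
    voiced_mask: np.ndarray

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0_hz[self.voiced_mask]

    @property
    def n_voiced(self) -> int:
        return int(np.count_nonzero(self.voiced_mask))


@dataclass(frozen=True)
class F0Stats:
    f0_min_hz: float
    f0_max_hz: float
    f0_range_st: float
    f0_sd_hz: float
    f0_level_hz: float


@dataclass(frozen=True)
class LoudnessStats:
    rms_level_db: float
    rms_sd_db: float


@dataclass(frozen=True)
class FormantStats:
    f1_hz: float
    f2_hz: float
    f3_hz: float


@dataclass(frozen=True)
class FormantTrack:
    """Per-voiced-frame formant estimates (NaN where not measurable)."""

    frame_times: np.ndarray
    f1_hz: np.ndarray
    f2_hz: np.ndarray
    f3_hz: np.ndarray


@dataclass(frozen=True)
class TiltStats:
    h1_h2_db: float
    h1_a1_db: float
    h1_a2_db: float
    h1_a3_db: float
    h1_h2_sd_db: float
    h1_a1_sd_db: float
    h1_a2_sd_db: float
    h1_a3_sd_db: float


@dataclass(frozen=True)
class ProsodyProfile:
    """The full per-reading feature vector plus provenance metadata."""

    speaker_id: str
    condition: str
    f0: F0Stats
    pauses: PauseStats
    speaking_rate_sps: float
    loudness: LoudnessStats
    formants: FormantStats
    tilt: TiltStats
    n_voiced_frames: int
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    warnings: tuple = ()

    def to_dict(self) -> dict:
        return {
            "speaker_id": self.speaker_id,
            "condition": self.condition,
            "f0_min_hz": self.f0.f0_min_hz,
            "f0_max_hz": self.f0.f0_max_hz,
            "f0_range_st": self.f0.f0_range_st,
            "f0_sd_hz": self.f0.f0_sd_hz,
            "f0_level_hz": self.f0.f0_level_hz,
            "n_pauses": self.pauses.n_pauses,
            "mean_pause_s": self.pauses.mean_pause_s,
            "speaking_rate_sps": self.speaking_rate_sps,
            "rms_level_db": self.loudness.rms_level_db,
            "rms_sd_db": self.loudness.rms_sd_db,
            "f1_hz": self.formants.f1_hz,
            "f2_hz": self.formants.f2_hz,
            "f3_hz": self.formants.f3_hz,
            "h1_h2_db": self.tilt.h1_h2_db,
            "h1_a1_db": self.tilt.h1_a1_db,
            "h1_a2_db": self.tilt.h1_a2_db,
            "h1_a3_db": self.tilt.h1_a3_db,
            "h1_h2_sd_db": self.tilt.h1_h2_sd_db,
            "h1_a1_sd_db": self.tilt.h1_a1_sd_db,
            "h1_a2_sd_db": self.tilt.h1_a2_sd_db,
            "h1_a3_sd_db": self.tilt.h1_a3_sd_db,
        }


#: Feature columns of the batch CSV, in export order.
FEATURE_COLUMNS = (
    "f0_min_hz",
    "f0_max_hz",
    "f0_range_st",
    "f0_sd_hz",
    "f0_level_hz",
    "n_pauses",
    "mean_pause_s",
    "speaking_rate_sps",
    "rms_level_db",
    "rms_sd_db",
    "f1_hz",
    "f2_hz",
    "f3_hz",
    "h1_h2_db",
    "h1_a1_db",
    "h1_a2_db",
    "h1_a3_db",
    "h1_h2_sd_db",
    "h1_a1_sd_db",
    "h1_a2_sd_db",
    "h1_a3_sd_db",
)


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Stack profiles into the batch feature table (one row per reading)."""
    rows = [p.to_dict() for p in profiles]
    return pd.DataFrame(rows, columns=["speaker_id", "condition", *FEATURE_COLUMNS])


# ---------------------------------------------------------------------------
# f0 tracking
# ---------------------------------------------------------------------------


def track_f0(
    signal: AudioSignal,
    floor_hz: float = 60.0,
    ceiling_hz: float = 500.0,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.45,
    silence_gate_db: float = 35.0,
    median_points: int = 5,
    refine: bool = True,
) -> F0Track:
    """Autocorrelation pitch tracker with voicing decision.

    Per 10 ms frame, the lag-corrected normalised autocorrelation is
    searched for its highest peak in the lag band
    ``[1/ceiling, 1/floor]``; the frame is voiced iff that peak is at
    least ``voicing_threshold`` and the frame intensity lies within
    ``silence_gate_db`` of the utterance's peak frame intensity. Lag is
    refined by parabolic interpolation and the voiced contour is cleaned
    with a short median filter to remove octave spikes.

    With ``refine`` (default), a second pass narrows the search band to
    [0.55, 1.8] times the first pass's median voiced f0 — the standard
    guard against locking onto a vocal-tract resonance, an octave, or a
    subharmonic when the search band is much wider than the speaker's
    actual range (read speech rarely exceeds +-8 semitones around its
    median).
    """
    track = _track_f0_once(
        signal, floor_hz, ceiling_hz, hop_s, voicing_threshold,
        silence_gate_db, median_points,
    )
    if refine and track.n_voiced >= 10:
        med = float(np.median(track.voiced_f0))
        lo = max(floor_hz, 0.55 * med)
        hi = min(ceiling_hz, 1.8 * med)
        if hi > lo:
            track = _track_f0_once(
                signal, lo, hi, hop_s, voicing_threshold,
                silence_gate_db, median_points,
            )
    return track


def _track_f0_once(
    signal: AudioSignal,
    floor_hz: float,
    ceiling_hz: float,
    hop_s: float,
    voicing_threshold: float,
    silence_gate_db: float,
    median_points: int,
) -> F0Track:
    if not floor_hz < ceiling_hz:
        raise ValueError("f0 floor must be below ceiling")
    fs = signal.rate
    frame_len_s = 2.5 / floor_hz  # >= 2.5 periods of the lowest f0
    n_len = int(round(frame_len_s * fs))
    n_hop = max(1, int(round(hop_s * fs)))
    x = signal.samples
    if n_len > x.size:
        return F0Track(
            frame_times=np.empty(0),
            f0_hz=np.empty(0),
            voiced_mask=np.empty(0, dtype=bool),
        )
    n_frames = (x.size - n_len) // n_hop + 1
    starts = n_hop * np.arange(n_frames)
    times = (starts + n_len / 2) / fs

    lag_min = max(2, int(np.floor(fs / ceiling_hz)))
    lag_max = int(np.ceil(fs / floor_hz))

    frames = x[starts[:, None] + np.arange(n_len)[None, :]]
    frames = frames - frames.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    with np.errstate(divide="ignore"):
        frame_db = 20.0 * np.log10(rms)
    peak_db = np.max(frame_db) if np.isfinite(frame_db).any() else -np.inf
    loud_enough = frame_db > peak_db - silence_gate_db
    # Periodicity estimates from frames riding a steep amplitude ramp
    # (syllable onsets/offsets at pause edges) lock onto fractional-
    # period peaks; require local stationarity instead.
    third = n_len // 3
    head_rms = np.sqrt(np.mean(frames[:, :third] ** 2, axis=1))
    tail_rms = np.sqrt(np.mean(frames[:, -third:] ** 2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ramp_db = np.abs(20.0 * np.log10(head_rms / tail_rms))
    stationary = np.isfinite(ramp_db) & (ramp_db <= 10.0)
    loud_enough &= stationary

    # FFT-based autocorrelation of all frames at once.
    nfft = int(2 ** np.ceil(np.log2(2 * n_len)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, : lag_max + 2]
    r0 = acf[:, 0].copy()
    r0[r0 <= 0] = np.inf
    nacf = acf / r0[:, None]
    # Peak selection uses the raw (biased) estimator, whose short-lag
    # preference guards against subharmonics; the voicing decision uses
    # the lag-corrected value so long-lag (low-f0) frames are not
    # penalised by the triangular bias.
    lags = np.arange(acf.shape[1])
    taper = np.maximum(1.0 - lags / n_len, 0.2)

    f0 = np.full(n_frames, np.nan)
    voiced = np.zeros(n_frames, dtype=bool)
    band = nacf[:, lag_min : lag_max + 1]
    best = np.argmax(band, axis=1) + lag_min
    best_val = nacf[np.arange(n_frames), best] / taper[best]
    for i in range(n_frames):
        if not loud_enough[i] or best_val[i] < voicing_threshold:
            continue
        lag = best[i]
        # parabolic interpolation around the peak
        if 1 <= lag < nacf.shape[1] - 1:
            ym1, y0, yp1 = nacf[i, lag - 1], nacf[i, lag], nacf[i, lag + 1]
            denom = ym1 - 2 * y0 + yp1
            delta = 0.5 * (ym1 - yp1) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        est = fs / (lag + delta)
        if floor_hz <= est <= ceiling_hz:
            f0[i] = est
            voiced[i] = True

    # Median-filter the voiced contour (as a subsequence, so spikes at
    # voiced-run edges are still surrounded by valid neighbours) to
    # remove octave and resonance-locking errors.
    if median_points > 1 and np.count_nonzero(voiced) >= 3:
        vals = f0[voiced]
        k = min(median_points, vals.size if vals.size % 2 else vals.size - 1)
        f0[voiced] = median_filter(vals, size=k, mode="reflect")

    return F0Track(frame_times=times, f0_hz=f0, voiced_mask=voiced)


def f0_statistics(
    track: F0Track,
    min_voiced_frames: int = 10,
    robust_extrema: bool = False,
) -> F0Stats:
    """Summarise a pitch track into min/max/range/sd/level.

    Extrema are the min and max of the cleaned voiced contour (or the
    5th/95th percentiles with ``robust_extrema``); the range is
    ``12*log2(max/min)`` semitones; sd and level are the population
    standard deviation and mean in Hz.
    """
    voiced = track.voiced_f0
    if voiced.size < min_voiced_frames:
        nan = math.nan
        return F0Stats(nan, nan, nan, nan, nan)
    if robust_extrema:
        f0_min, f0_max = np.percentile(voiced, [5.0, 95.0])
    else:
        f0_min, f0_max = float(np.min(voiced)), float(np.max(voiced))
    return F0Stats(
        f0_min_hz=float(f0_min),
        f0_max_hz=float(f0_max),
        f0_range_st=float(12.0 * np.log2(f0_max / f0_min)),
        f0_sd_hz=float(np.std(voiced)),
        f0_level_hz=float(np.mean(voiced)),
    )


# ---------------------------------------------------------------------------
# loudness
# ---------------------------------------------------------------------------


def loudness_stats(
    signal: AudioSignal,
    track: SegmentTrack,
    window_s: float = 0.020,
    calibration_offset_db: float = 0.0,
) -> LoudnessStats:
    """RMS loudness level and variability over speech intervals.

    Non-overlapping windows (default 20 ms) are cut from the speech
    intervals only; the level is the mean of the per-window dB values
    (dB re full scale plus the calibration offset) and the variability is
    their population standard deviation, which is offset-invariant.
    """
    fs = signal.rate
    n_win = max(1, int(round(window_s * fs)))
    db_values = []
    for start, end in track.speech_intervals:
        # windows snap to a global grid (multiples of the window length
        # from t = 0) so measurements are stable under silence padding
        i0 = int(np.ceil(round(start * fs) / n_win)) * n_win
        i1 = int(round(end * fs))
        seg = signal.samples[i0:i1]
        n_full = seg.size // n_win
        if n_full == 0:
            continue
        windows = seg[: n_full * n_win].reshape(n_full, n_win)
        rms = np.sqrt(np.mean(windows**2, axis=1))
        rms = rms[rms > 0]
        db_values.append(20.0 * np.log10(rms))
    if not db_values:
        return LoudnessStats(math.nan, math.nan)
    db = np.concatenate(db_values)
    return LoudnessStats(
        rms_level_db=float(np.mean(db)) + calibration_offset_db,
        rms_sd_db=float(np.std(db)),
    )


# ---------------------------------------------------------------------------
# formants
# ---------------------------------------------------------------------------


def _lpc_autocorrelation(frame: np.ndarray, order: int) -> np.ndarray | None:
    """LPC coefficients via the autocorrelation (Yule-Walker) method."""
    r = np.correlate(frame, frame, mode="full")[frame.size - 1 : frame.size + order]
    if r[0] <= 0:
        return None
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    except np.linalg.LinAlgError:
        return None
    return np.concatenate(([1.0], a))


def estimate_formants(
    signal: AudioSignal,
    f0_track: F0Track,
    n_formants: int = 3,
    lpc_order: int = 12,
    analysis_rate_hz: float = 10_000.0,
    pre_emphasis: float = 0.97,
    max_bandwidth_hz: float = 700.0,
    freq_range_hz: tuple = (90.0, 4500.0),
    min_valid_frames: int = 10,
) -> tuple[FormantStats, FormantTrack]:
    """Estimate F1–F3 levels by LPC root-solving on voiced frames.

    The signal is resampled to the 10 kHz analysis rate and pre-emphasised;
    per voiced frame a 25 ms Hamming window is fit with an order-12
    all-pole model (autocorrelation method). Polynomial roots with
    frequency in [90, 4500] Hz and bandwidth at most
    ``min(max_bandwidth_hz, f/2)`` — an absolute cap plus a minimum-Q
    requirement that rejects broad spectral-shape roots while keeping
    genuine higher formants, whose estimated bandwidths inflate under
    pre-emphasis — are sorted ascending as formant candidates. Levels
    are means over frames where all three formants were found; fewer
    than ``min_valid_frames`` such frames yields NaN levels.
    """
    fs = signal.rate
    if fs > analysis_rate_hz:
        from fractions import Fraction

        frac = Fraction(int(round(analysis_rate_hz)), int(round(fs))).limit_denominator(1000)
        x = resample_poly(signal.samples, frac.numerator, frac.denominator)
        fs_a = fs * frac.numerator / frac.denominator
    else:
        x = signal.samples
        fs_a = fs
    x = np.concatenate(([x[0] * (1 - pre_emphasis)], x[1:] - pre_emphasis * x[:-1]))

    n_len = int(round(0.025 * fs_a))
    window = np.hamming(n_len)
    half = n_len // 2

    times = f0_track.frame_times[f0_track.voiced_mask]
    f123 = np.full((times.size, 3), np.nan)
    lo, hi = freq_range_hz
    nfft = 2048
    fft_freqs = np.fft.rfftfreq(nfft, d=1.0 / fs_a)
    for k, t in enumerate(times):
        centre = int(round(t * fs_a))
        i0 = centre - half
        if i0 < 0 or i0 + n_len > x.size:
            continue
        frame = x[i0 : i0 + n_len] * window
        a = _lpc_autocorrelation(frame, lpc_order)
        if a is None:
            continue
        roots = np.roots(a)
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * fs_a / (2 * np.pi)
        with np.errstate(divide="ignore"):
            bws = -np.log(np.abs(roots)) * fs_a / np.pi
        keep = (
            (bws <= np.minimum(max_bandwidth_hz, freqs / 2.0))
            & (freqs >= lo)
            & (freqs <= hi)
        )
        cand = np.sort(freqs[keep])
        if cand.size < n_formants:
            continue
        # formants are only measurable from harmonically rich excitation:
        # a vowel frame shows many resolved harmonic peaks within ~45 dB
        # of its maximum, whereas a line spectrum (e.g. a pure tone)
        # shows one and its LPC roots are phantoms
        f0_here = float(f0_track.voiced_f0[k])
        mag = np.abs(np.fft.rfft(frame, nfft)) + 1e-30
        mag_db = 20.0 * np.log10(mag)
        min_dist = max(1, int(0.6 * f0_here / (fs_a / nfft)))
        peaks, _ = find_peaks(
            mag_db, height=mag_db.max() - 45.0, distance=min_dist
        )
        if peaks.size < 4:
            continue
        f123[k] = cand[:n_formants]

    # light median smoothing per track removes frame-to-frame picking
    # jitter between neighbouring root configurations
    valid = ~np.isnan(f123).any(axis=1)
    if np.count_nonzero(valid) >= 3:
        sub = f123[valid]
        ksize = min(5, sub.shape[0] if sub.shape[0] % 2 else sub.shape[0] - 1)
        for col in range(3):
            sub[:, col] = median_filter(sub[:, col], size=ksize, mode="reflect")
        f123[valid] = sub
    if np.count_nonzero(valid) < min_valid_frames:
        stats = FormantStats(math.nan, math.nan, math.nan)
    else:
        means = f123[valid].mean(axis=0)
        stats = FormantStats(*[float(v) for v in means])
    trackout = FormantTrack(
        frame_times=times,
        f1_hz=f123[:, 0],
        f2_hz=f123[:, 1],
        f3_hz=f123[:, 2],
    )
    return stats, trackout


# ---------------------------------------------------------------------------
# spectral tilt
# ---------------------------------------------------------------------------


def harmonic_amplitudes(
    frame: np.ndarray,
    rate: float,
    f0: float,
    formants: tuple,
) -> tuple:
    """Measure H1, H2 and A1–A3 (dB) from one voiced frame.

    The magnitude spectrum is taken with a Hann window zero-padded x4.
    H1/H2 are the peak magnitudes within ±f0/4 of f0 and 2 f0; each Ak is
    the magnitude of the strongest harmonic peak within ±f0/2 of formant
    Fk (ties broken toward the lower harmonic). Unmeasurable values are
    NaN.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size < 4 * rate / f0:
        raise ValueError("frame shorter than 4 periods of f0")
    windowed = (frame - frame.mean()) * np.hanning(frame.size)
    nfft = 4 * frame.size
    mag = np.abs(rfft(windowed, n=nfft))
    freqs = rfftfreq(nfft, d=1.0 / rate)

    def peak_db(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            return math.nan
        idx = np.where(sel)[0]
        j = idx[np.argmax(mag[idx])]
        if j == idx[0] or j == idx[-1]:  # peak at window edge: unreliable
            if 0 < j < mag.size - 1 and mag[j] >= mag[j - 1] and mag[j] >= mag[j + 1]:
                pass  # genuine local maximum that happens to sit at the edge
            else:
                return math.nan
        m = mag[j]
        return 20.0 * math.log10(m) if m > 0 else math.nan

    h1 = peak_db(f0 - f0 / 4, f0 + f0 / 4)
    h2 = peak_db(2 * f0 - f0 / 4, 2 * f0 + f0 / 4)

    a_values = []
    for fk in formants:
        if fk is None or not np.isfinite(fk):
            a_values.append(math.nan)
            continue
        m_lo = int(np.ceil((fk - f0 / 2) / f0))
        m_hi = int(np.floor((fk + f0 / 2) / f0))
        best_db = math.nan
        for m in range(max(1, m_lo), m_hi + 1):
            db = peak_db(m * f0 - f0 / 4, m * f0 + f0 / 4)
            # strict > keeps the lower harmonic on ties
            if not math.isnan(db) and (math.isnan(best_db) or db > best_db):
                best_db = db
        a_values.append(best_db)
    return (h1, h2, *a_values)


def spectral_tilt_stats(
    signal: AudioSignal,
    f0_track: F0Track,
    formant_track: FormantTrack,
) -> TiltStats:
    """Levels and variabilities of H1-H2 and H1-A1..A3 over voiced frames.

    Frames lacking a target (no f0, missing formant, unmeasurable peak)
    are excluded pairwise per measure; a measure with no valid frame is
    NaN. Variability is the population standard deviation.
    """
    fs = signal.rate
    times = f0_track.frame_times[f0_track.voiced_mask]
    f0s = f0_track.voiced_f0
    fmap = {round(float(t), 6): i for i, t in enumerate(formant_track.frame_times)}

    diffs = {k: [] for k in ("h1_h2", "h1_a1", "h1_a2", "h1_a3")}
    x = signal.samples
    for t, f0 in zip(times, f0s):
        if not np.isfinite(f0) or f0 <= 0:
            continue
        # 6 periods keep the Hann mainlobe well under the harmonic
        # spacing, so weak high harmonics are not polluted by leakage
        win_s = max(6.0 / f0, 0.040)
        n_len = int(round(win_s * fs))
        centre = int(round(t * fs))
        i0 = centre - n_len // 2
        if i0 < 0 or i0 + n_len > x.size:
            continue
        # harmonic measurement assumes local stationarity: skip frames
        # riding an amplitude ramp (syllable onset/offset)
        head = x[i0 : i0 + n_len // 3]
        tail = x[i0 + 2 * (n_len // 3) : i0 + n_len]
        head_rms, tail_rms = np.sqrt(np.mean(head**2)), np.sqrt(np.mean(tail**2))
        if head_rms <= 0 or tail_rms <= 0:
            continue
        if abs(20.0 * math.log10(head_rms / tail_rms)) > 6.0:
            continue
        # impulsive transients (clicks, plosive bursts) violate the
        # quasi-periodic assumption behind harmonic measurement
        whole = x[i0 : i0 + n_len]
        if np.max(np.abs(whole)) > 8.0 * np.sqrt(np.mean(whole**2)):
            continue
        idx = fmap.get(round(float(t), 6))
        if idx is None:
            formants = (math.nan, math.nan, math.nan)
        else:
            formants = (
                formant_track.f1_hz[idx],
                formant_track.f2_hz[idx],
                formant_track.f3_hz[idx],
            )
        try:
            h1, h2, a1, a2, a3 = harmonic_amplitudes(
                x[i0 : i0 + n_len], fs, float(f0), formants
            )
        except ValueError:
            continue
        if not (math.isnan(h1) or math.isnan(h2)):
            diffs["h1_h2"].append(h1 - h2)
        for key, ak in (("h1_a1", a1), ("h1_a2", a2), ("h1_a3", a3)):
            if not (math.isnan(h1) or math.isnan(ak)):
                diffs[key].append(h1 - ak)

    def level_sd(vals) -> tuple:
        if not vals:
            return math.nan, math.nan
        arr = np.asarray(vals)
        return float(arr.mean()), float(arr.std())

    h1h2, h1h2_sd = level_sd(diffs["h1_h2"])
    h1a1, h1a1_sd = level_sd(diffs["h1_a1"])
    h1a2, h1a2_sd = level_sd(diffs["h1_a2"])
    h1a3, h1a3_sd = level_sd(diffs["h1_a3"])
    return TiltStats(h1h2, h1a1, h1a2, h1a3, h1h2_sd, h1a1_sd, h1a2_sd, h1a3_sd)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def extract_profile(
    signal: AudioSignal,
    config: AnalysisConfig | None = None,
    speaker_id: str = "",
    condition: str = "",
) -> ProsodyProfile:
    """Run the full extraction chain on one (already normalised) reading.

    Stage failures become NaN fields with a recorded warning; the call
    itself never raises for short or degenerate audio, so batch runs can
    continue past individual bad files.
    """
    cfg = config or AnalysisConfig()
    warnings: list[str] = []
    nan = math.nan

    try:
        track = detect_pauses(
            signal,
            silence_threshold_db=cfg.silence_threshold_db,
            min_pause_s=cfg.min_pause_s,
            min_speech_s=cfg.min_speech_s,
        )
        if track.warning:
            warnings.append(track.warning)
    except ValueError as exc:
        warnings.append(f"segmentation failed: {exc}")
        track = None

    f0_track = track_f0(
        signal,
        floor_hz=cfg.f0_floor_hz,
        ceiling_hz=cfg.f0_ceiling_hz,
        hop_s=cfg.f0_hop_s,
        voicing_threshold=cfg.voicing_threshold,
        silence_gate_db=cfg.silence_gate_db,
        median_points=cfg.median_filter_points,
    )
    f0_stats = f0_statistics(
        f0_track,
        min_voiced_frames=cfg.min_voiced_frames,
        robust_extrema=cfg.robust_f0_extrema,
    )
    if math.isnan(f0_stats.f0_level_hz):
        warnings.append(
            f"fewer than {cfg.min_voiced_frames} voiced frames; f0 undefined"
        )

    if track is not None:
        p_stats = pause_stats(track)
        loud = loudness_stats(
            signal,
            track,
            window_s=cfg.loudness_window_s,
            calibration_offset_db=cfg.calibration_offset_db,
        )
        if math.isnan(loud.rms_level_db):
            warnings.append("no speech windows; loudness undefined")
        try:
            n_syll = count_syllable_nuclei(
                signal,
                track,
                voiced_mask=f0_track.voiced_mask,
                mask_times=f0_track.frame_times,
            )
            rate = (
                speaking_rate(n_syll, track, include_pauses=cfg.include_pauses_in_rate)
                if track.total_speech_time > 0
                else nan
            )
        except ValueError as exc:
            warnings.append(f"speaking rate undefined: {exc}")
            rate = nan
    else:
        p_stats = PauseStats(0, nan, 0.0)
        loud = LoudnessStats(nan, nan)
        rate = nan

    if f0_track.n_voiced >= cfg.min_voiced_frames:
        formant_stats, formant_track = estimate_formants(
            signal,
            f0_track,
            n_formants=cfg.n_formants,
            lpc_order=cfg.lpc_order,
            analysis_rate_hz=cfg.formant_rate_hz,
            pre_emphasis=cfg.pre_emphasis,
            max_bandwidth_hz=cfg.max_formant_bandwidth_hz,
            freq_range_hz=cfg.formant_freq_range_hz,
            min_valid_frames=cfg.min_voiced_frames,
        )
        if math.isnan(formant_stats.f1_hz):
            warnings.append("too few frames with three valid formants")
        tilt = spectral_tilt_stats(signal, f0_track, formant_track)
    else:
        formant_stats = FormantStats(nan, nan, nan)
        tilt = TiltStats(nan, nan, nan, nan, nan, nan, nan, nan)

    return ProsodyProfile(
        speaker_id=speaker_id,
        condition=condition,
        f0=f0_stats,
        pauses=p_stats,
        speaking_rate_sps=rate,
        loudness=loud,
        formants=formant_stats,
        tilt=tilt,
        n_voiced_frames=f0_track.n_voiced,
        config=cfg,
        warnings=tuple(warnings),
    )
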