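"""Source-filter speech synthesis and simulated before/after cohorts.

Every quantity the feature extractor measures can be programmed here, so
each pipeline stage is testable by parameter recovery: an impulse-train
glottal source whose first-to-second-harmonic ratio is solved
analytically from the spectral-tilt target, a cascade of second-order
formant resonators, a syllable-modulated amplitude envelope, and silent
pauses laid out explicitly.

The cohort generator emulates the study design the statistics stage
expects: three treatment arms (VBRO, MEDI, CONT) of ten speakers each,
seven female and three male per arm, one BEF and one AFT reading per
speaker, with arm-specific BEF-to-AFT shifts. The control-arm preset
anchors the loudness drop at +4.5 dB (readings become softer after the
waiting period); the remaining magnitudes are synthetic calibration
values chosen to reproduce the directions of the treatment effects, not
measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import freqz, lfilter
from scipy.signal.windows import tukey

from .audio_io import AudioSignal, CohortManifest, write_wav
from .prosody_features import FEATURE_COLUMNS

__all__ = [
    "UtteranceSpec",
    "UtteranceTruth",
    "CohortDesign",
    "EffectPreset",
    "default_effect_presets",
    "tilt_filter_coefficient",
    "synthesize_utterance",
    "build_reading_spec",
    "simulate_cohort_features",
    "simulate_cohort_audio",
]


# ---------------------------------------------------------------------------
# source spectral-tilt control
# ---------------------------------------------------------------------------


def _one_pole_drop_db(a: float, f0: float, fs: float) -> float:
    """H1-to-H2 gain difference (dB) of the one-pole filter 1/(1 - a z^-1)."""
    w1 = 2 * math.pi * f0 / fs
    w2 = 2 * w1
    num = 1 - 2 * a * math.cos(w2) + a * a
    den = 1 - 2 * a * math.cos(w1) + a * a
    return 10.0 * math.log10(num / den)


def tilt_filter_coefficient(h1_h2_db: float, f0: float, fs: float) -> tuple:
    """Solve the source shaping filter for a target H1-H2 (dB).

    The source is an impulse train (flat harmonics); its tilt is shaped
    by a double real pole at ``z = a`` for positive targets (energy
    falls with frequency, breathier) or a double real zero for negative
    targets (energy rises, pressed). Each first-order section can span
    just under 6.02 dB between f0 and 2 f0, so the reachable target
    range is about (-12, +12) dB.

    Returns ``(kind, a)`` with ``kind`` in {"pole", "zero"}.
    """
    limit = 2 * _one_pole_drop_db(1 - 1e-9, f0, fs)
    target = float(np.clip(h1_h2_db, -limit + 1e-6, limit - 1e-6))
    per_section = abs(target) / 2.0
    if per_section < 1e-12:
        return ("pole", 0.0)
    a = brentq(
        lambda a_: _one_pole_drop_db(a_, f0, fs) - per_section, 0.0, 1 - 1e-9
    )
    return ("pole" if target >= 0 else "zero", float(a))


def _tilt_filter_apply(x: np.ndarray, kind: str, a: float) -> np.ndarray:
    if a == 0.0:
        return x
    if kind == "pole":
        return lfilter([1.0], [1.0, -a], lfilter([1.0], [1.0, -a], x))
    return lfilter([1.0, -a], [1.0], lfilter([1.0, -a], [1.0], x))


def _tilt_filter_response_db(kind: str, a: float, f: float, fs: float) -> float:
    """Filter magnitude (dB) at frequency ``f``."""
    w = 2 * math.pi * f / fs
    mag_sq = 1 - 2 * a * math.cos(w) + a * a
    one = -10.0 * math.log10(mag_sq) if kind == "pole" else 10.0 * math.log10(mag_sq)
    return 2 * one


def _rosenberg_derivative(f0: float, fs: float, open_frac: float = 0.4,
                          close_frac: float = 0.16) -> np.ndarray:
    """One glottal-flow-derivative pulse (Rosenberg shape) at period 1/f0.

    The derivative of the rising/falling flow pulse carries the natural
    high-frequency rolloff of a glottal source (plus lip radiation), so
    downstream all-pole analysis sees realistically conditioned spectra.
    """
    T = 1.0 / f0
    t_open, t_close = open_frac * T, close_frac * T
    n = max(4, int(round((t_open + t_close) * fs)))
    t = np.arange(n) / fs
    flow = np.where(
        t <= t_open,
        0.5 * (1 - np.cos(np.pi * t / t_open)),
        np.cos((t - t_open) * np.pi / (2 * t_close)),
    )
    return np.diff(flow, prepend=0.0)


def _pulse_tilt_db(pulse: np.ndarray, f0: float, fs: float) -> float:
    """H1-to-H2 drop (dB) contributed by a source pulse's spectrum."""
    nfft = int(round(fs))
    spectrum = np.abs(np.fft.rfft(pulse, nfft))
    return 20.0 * math.log10(
        spectrum[int(round(f0))] / spectrum[int(round(2 * f0))]
    )


def _resonator_coeffs(f_hz: float, bw_hz: float, fs: float) -> tuple:
    """Klatt-style second-order resonator (unity gain at resonance-ish)."""
    r = math.exp(-math.pi * bw_hz / fs)
    theta = 2 * math.pi * f_hz / fs
    a1, a2 = 2 * r * math.cos(theta), -(r * r)
    b0 = 1 - a1 - a2  # unity DC gain
    return np.array([b0]), np.array([1.0, -a1, -a2])


# ---------------------------------------------------------------------------
# utterance specification and synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UtteranceSpec:
    """Complete programme for one synthetic reading.

    The f0 contour is a slow sinusoid between
    ``level * 2**(-range_st/24)`` and ``level * 2**(+range_st/24)``
    (linear in Hz, so its time average is the midpoint). Syllables are
    flat-top amplitude bumps at ``syllable_times`` with per-syllable
    peak levels ``syllable_amps_db`` (dB re the loudest syllable);
    ``pauses`` are internal silent intervals. The annotation reports
    contour statistics restricted to where speech actually sounds.
    """

    duration_s: float
    sample_rate: float = 48_000.0
    f0_level_hz: float = 200.0
    f0_range_st: float = 8.0
    f0_mod_hz: float = 0.8
    h1_h2_db: float = 6.0
    formants_hz: tuple = (500.0, 1500.0, 2500.0)
    bandwidths_hz: tuple = (80.0, 100.0, 120.0)
    syllable_times: tuple = ()
    syllable_amps_db: tuple = ()
    syllable_width_s: float = 0.22
    syllable_ramp_s: float = 0.03  # rise/fall of the flat-top syllable window
    pauses: tuple = ()  # internal (start_s, end_s) silences
    peak_amplitude: float = 0.9

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("utterance duration must be positive")
        nyquist = self.sample_rate / 2
        f0_max = self.f0_level_hz * 2 ** (self.f0_range_st / 24.0)
        if f0_max > nyquist / 4:
            raise ValueError("f0 too high for the sample rate (above Nyquist/4)")
        if max(self.formants_hz) >= nyquist:
            raise ValueError("formant target above Nyquist")
        if len(self.syllable_times) != len(self.syllable_amps_db):
            raise ValueError("syllable times and amplitudes must align")
        prev_end = 0.0
        for s, e in self.pauses:
            if not (0 <= s < e <= self.duration_s):
                raise ValueError("pause outside utterance bounds")
            if s < prev_end:
                raise ValueError("pauses must be non-overlapping and ordered")
            prev_end = e
        if list(self.formants_hz) != sorted(self.formants_hz):
            raise ValueError("formants must be ascending")


@dataclass(frozen=True)
class UtteranceTruth:
    """Programmed ground truth for every extractable quantity."""

    f0_level_hz: float
    f0_min_hz: float
    f0_max_hz: float
    f0_range_st: float
    h1_h2_db: float  # source tilt plus formant-cascade contribution at f0 level
    source_h1_h2_db: float
    formants_hz: tuple
    n_pauses: int
    mean_pause_s: float
    n_syllables: int
    speech_span_s: float
    mean_syllable_amp_db: float


def synthesize_utterance(spec: UtteranceSpec) -> tuple:
    """Render a spec to audio and return (AudioSignal, UtteranceTruth).

    Pipeline: impulse-train source following the f0 contour; double
    pole/zero tilt shaping solved from the H1-H2 target; cascaded
    formant resonators; syllable envelope and pauses; peak scaling.
    """
    fs = spec.sample_rate
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs

    f0_lo = spec.f0_level_hz * 2.0 ** (-spec.f0_range_st / 24.0)
    f0_hi = spec.f0_level_hz * 2.0 ** (spec.f0_range_st / 24.0)
    mid, amp = (f0_lo + f0_hi) / 2.0, (f0_hi - f0_lo) / 2.0
    f0_t = mid + amp * np.sin(2 * math.pi * spec.f0_mod_hz * t - math.pi / 2)

    # impulse train by phase accumulation, convolved with a glottal
    # flow-derivative pulse for a natural source rolloff
    phase = np.cumsum(f0_t / fs)
    source = np.zeros(n)
    source[np.flatnonzero(np.diff(np.floor(phase)) > 0) + 1] = 1.0
    if not source.any():
        raise ValueError("no glottal pulses generated")
    pulse = _rosenberg_derivative(spec.f0_level_hz, fs)
    source = np.convolve(source, pulse)[:n]

    # the adjustment filter is solved for the residual tilt after the
    # pulse's own H1-H2 contribution, so the combined source meets the
    # programmed target exactly at the contour's level frequency
    pulse_tilt = _pulse_tilt_db(pulse, spec.f0_level_hz, fs)
    kind, a = tilt_filter_coefficient(
        spec.h1_h2_db - pulse_tilt, spec.f0_level_hz, fs
    )
    shaped = _tilt_filter_apply(source, kind, a)

    out = shaped
    num_all, den_all = np.array([1.0]), np.array([1.0])
    for f_hz, bw in zip(spec.formants_hz, spec.bandwidths_hz):
        b, aden = _resonator_coeffs(f_hz, bw, fs)
        out = lfilter(b, aden, out)
        num_all = np.convolve(num_all, b)
        den_all = np.convolve(den_all, aden)

    # envelope: flat-top (Tukey) bump per syllable, silence elsewhere;
    # the short ramps keep the silent gaps sharp for pause marking
    env = np.zeros(n)
    width = int(round(spec.syllable_width_s * fs))
    alpha = min(1.0, 2 * spec.syllable_ramp_s / spec.syllable_width_s)
    window = tukey(width, alpha)
    for time_s, amp_db in zip(spec.syllable_times, spec.syllable_amps_db):
        centre = int(round(time_s * fs))
        i0 = centre - width // 2
        j0, j1 = max(i0, 0), min(i0 + width, n)
        if j1 <= j0:
            continue
        env[j0:j1] = np.maximum(env[j0:j1], window[j0 - i0 : j1 - i0] * 10 ** (amp_db / 20.0))
    for s, e in spec.pauses:
        env[int(round(s * fs)) : int(round(e * fs))] = 0.0
    out = out * env

    # A stress transient (plosive-like click) at the loudest syllable
    # pins the waveform peak to a fixed multiple of that syllable's RMS.
    # Without it the crest factor drifts with the source tilt (tenser
    # voices are spikier), which would leak voice-quality changes into
    # peak-normalised loudness measurements.
    if len(spec.syllable_amps_db):
        j = int(np.argmax(spec.syllable_amps_db))
        centre = int(round(spec.syllable_times[j] * fs))
        quarter = max(1, width // 4)
        lo = max(0, centre - quarter)
        plateau = out[lo : centre + quarter]
        rms_anchor = float(np.sqrt(np.mean(plateau**2))) if plateau.size else 0.0
        if rms_anchor > 0 and centre + 1 < n:
            click = 12.0 * rms_anchor  # ~21.6 dB above the anchor RMS
            out[centre] += click
            out[centre + 1] -= click

    peak = np.max(np.abs(out))
    if peak > 0:
        out = out * (spec.peak_amplitude / peak)

    # Ground truth is evaluated on the programmed contour restricted to
    # where speech actually sounds (the support of the envelope), which
    # is what the frame-wise measurements average over. H1-H2 truth =
    # source-filter tilt plus the formant-cascade contribution between
    # f0 and 2 f0, averaged along the contour; both are known
    # analytically from the filter coefficients.
    step = max(1, int(round(0.005 * fs)))
    support = env[::step] > 0
    f0_sup = f0_t[::step][support]
    if f0_sup.size == 0:
        f0_sup = f0_t[::step]
    source_tilt_pts = np.array(
        [
            _tilt_filter_response_db(kind, a, f, fs)
            - _tilt_filter_response_db(kind, a, 2 * f, fs)
            + _pulse_tilt_db(pulse, f, fs)
            for f in f0_sup
        ]
    )
    w_eval = 2 * math.pi * np.concatenate([f0_sup, 2 * f0_sup]) / fs
    _, h = freqz(num_all, den_all, worN=w_eval)
    hmag = 20.0 * np.log10(np.abs(h))
    cascade_tilt_pts = hmag[: f0_sup.size] - hmag[f0_sup.size :]
    source_tilt = float(source_tilt_pts.mean())
    cascade_tilt = float(cascade_tilt_pts.mean())

    # Pause ground truth comes from the rendered envelope: silent gaps
    # between syllable supports of at least 0.25 s are internal pauses.
    amps = np.asarray(spec.syllable_amps_db, dtype=float)
    syl = np.sort(np.asarray(spec.syllable_times, dtype=float))
    half_w = spec.syllable_width_s / 2
    gaps = []
    for t_prev, t_next in zip(syl[:-1], syl[1:]):
        gap = (t_prev + half_w, t_next - half_w)
        if gap[1] - gap[0] >= 0.25:
            gaps.append(gap)
    true_min, true_max = float(f0_sup.min()), float(f0_sup.max())
    truth = UtteranceTruth(
        f0_level_hz=float(f0_sup.mean()),
        f0_min_hz=true_min,
        f0_max_hz=true_max,
        f0_range_st=float(12.0 * math.log2(true_max / true_min)),
        h1_h2_db=source_tilt + cascade_tilt,
        source_h1_h2_db=source_tilt,
        formants_hz=spec.formants_hz,
        n_pauses=len(gaps),
        mean_pause_s=float(np.mean([e - s for s, e in gaps])) if gaps else math.nan,
        n_syllables=len(syl),
        speech_span_s=float(syl.max() - syl.min() + spec.syllable_width_s)
        if syl.size
        else 0.0,
        mean_syllable_amp_db=float(amps.mean()) if amps.size else math.nan,
    )
    return AudioSignal(samples=out, rate=fs, source_id="synthetic"), truth


@dataclass(frozen=True)
class ReadingLayout:
    """Text-dependent part of a reading: syllable grid, stress pattern
    (standardised per-syllable level deviates), anchor syllable, pauses.

    The same layout reused for a speaker's BEF and AFT readings emulates
    reading the same text twice, so condition differences come only from
    the programmed voice parameters.
    """

    duration_s: float
    syllable_times: tuple
    z_amps: tuple  # standard-normal deviates, one per syllable
    anchor: int
    pauses: tuple


def build_reading_layout(
    duration_s: float,
    rng: np.random.Generator,
    n_pauses: int = 3,
    pause_duration_range_s: tuple = (0.4, 0.8),
    syllable_rate_sps: float = 4.0,
    lead_silence_s: float = 0.3,
) -> ReadingLayout:
    """Draw a reading-like syllable/pause layout.

    Internal pauses split the speech span into chunks of at least one
    second; syllables sit at the given rate inside each chunk.
    """
    period = 1.0 / syllable_rate_sps
    speech_end = duration_s - lead_silence_s
    pause_durs = rng.uniform(*pause_duration_range_s, size=n_pauses)
    centres = np.sort(
        rng.uniform(lead_silence_s + 1.5, max(lead_silence_s + 1.6, speech_end - 1.5),
                    size=n_pauses)
    )
    pauses = []
    prev_end = lead_silence_s
    for c, d in zip(centres, pause_durs):
        s, e = c - d / 2, c + d / 2
        if s < prev_end + 1.0:  # keep >= 1 s of speech between pauses
            s = prev_end + 1.0
            e = s + d
        if e > speech_end - 1.0:
            break
        pauses.append((float(s), float(e)))
        prev_end = e

    chunk_bounds = [lead_silence_s]
    for s, e in pauses:
        chunk_bounds += [s, e]
    chunk_bounds.append(speech_end)

    times = []
    for c0, c1 in zip(chunk_bounds[::2], chunk_bounds[1::2]):
        t0 = c0 + period / 2
        while t0 + period / 2 <= c1:
            times.append(t0)
            t0 += period
    z = rng.standard_normal(len(times))
    anchor = int(rng.integers(len(times)))
    return ReadingLayout(
        duration_s=duration_s,
        syllable_times=tuple(times),
        z_amps=tuple(float(v) for v in z),
        anchor=anchor,
        pauses=tuple(pauses),
    )


def build_reading_spec(
    duration_s: float,
    rng: np.random.Generator,
    sample_rate: float = 48_000.0,
    f0_level_hz: float = 200.0,
    f0_range_st: float = 8.0,
    h1_h2_db: float = 6.0,
    formants_hz: tuple = (500.0, 1500.0, 2500.0),
    n_pauses: int = 3,
    amp_sd_db: float = 2.5,
    soft_db: float = 0.0,
    layout: ReadingLayout | None = None,
) -> UtteranceSpec:
    """Assemble an utterance spec from voice parameters and a layout.

    Syllable peak levels are ``-3 + z * amp_sd_db`` dB re max (capped at
    -0.5 dB). ``soft_db`` lowers every syllable except the single
    "anchor", which stays at 0 dB: this emulates quieter speech whose
    occasional stressed peaks still reach the recording's dynamic-range
    ceiling, so the level change survives per-file peak normalisation.
    When ``layout`` is omitted one is drawn from ``rng``.
    """
    if layout is None:
        layout = build_reading_layout(duration_s, rng, n_pauses=n_pauses)
    amps = -3.0 + np.asarray(layout.z_amps) * amp_sd_db
    amps = np.minimum(amps, -0.5)  # keep below the anchor
    amps = amps - soft_db  # softer overall ...
    amps[layout.anchor] = 0.0  # ... but the anchor still hits the ceiling
    return UtteranceSpec(
        duration_s=layout.duration_s,
        sample_rate=sample_rate,
        f0_level_hz=f0_level_hz,
        f0_range_st=f0_range_st,
        h1_h2_db=h1_h2_db,
        formants_hz=tuple(formants_hz),
        syllable_times=layout.syllable_times,
        syllable_amps_db=tuple(float(v) for v in amps),
        pauses=layout.pauses,
    )


# ---------------------------------------------------------------------------
# cohort design, effect presets, feature-level simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectPreset:
    """BEF-to-AFT shift of one treatment arm.

    ``feature_effects`` maps feature columns to the expected
    within-speaker difference (BEF - AFT, the feature's native units); a
    positive entry means the feature is lower after treatment.
    ``audio`` holds the subset of shifts the waveform synthesiser can
    realise directly.
    """

    name: str
    feature_effects: dict
    audio: dict

    def with_scale(self, scale: float) -> "EffectPreset":
        return EffectPreset(
            name=self.name,
            feature_effects={k: v * scale for k, v in self.feature_effects.items()},
            audio={k: v * scale for k, v in self.audio.items()},
        )


def _effects(**kwargs) -> dict:
    base = {c: 0.0 for c in FEATURE_COLUMNS}
    base.update(kwargs)
    return base


def default_effect_presets() -> dict:
    """Per-arm BEF-to-AFT effect vectors reproducing the study directions.

    Control arm (CONT): f0 minimum and level drop after the waiting
    period (positive diffs), the f0 range widens (negative diff via a
    lower minimum and higher maximum), the voice becomes tenser (all four
    spectral-tilt diffs positive), and the reading gets 4.5 dB softer
    with less loudness variability. The two intervention arms (VBRO,
    MEDI) share one preset — near-zero shifts with slightly negative
    tilt diffs (breathier after treatment) and a small loudness-
    variability shrink — so their pairwise contrast is null by
    construction. A ``null`` preset (all zeros) supports type-I-error
    calibration. Only the 4.5 dB loudness anchor tracks a reported
    magnitude; all other magnitudes are synthetic calibration values.
    """
    cont = EffectPreset(
        name="CONT",
        feature_effects=_effects(
            f0_min_hz=8.0,
            f0_max_hz=-4.0,
            f0_sd_hz=-2.0,
            f0_level_hz=5.0,
            h1_h2_db=2.0,
            h1_a1_db=2.0,
            h1_a2_db=2.5,
            h1_a3_db=3.0,
            rms_level_db=4.5,
            rms_sd_db=1.5,
        ),
        audio=dict(
            f0_level_shift_hz=6.0,
            f0_range_shift_st=-1.0,
            h1_h2_shift_db=2.5,
            rms_shift_db=4.5,
            amp_sd_shift_db=0.8,
        ),
    )
    intervention = EffectPreset(
        name="VBRO",
        feature_effects=_effects(
            f0_min_hz=-0.5,
            f0_max_hz=1.0,
            f0_sd_hz=0.3,
            f0_level_hz=0.5,
            h1_h2_db=-0.8,
            h1_a1_db=-0.8,
            h1_a2_db=-0.8,
            h1_a3_db=-0.8,
            rms_level_db=0.5,
            rms_sd_db=0.5,
        ),
        audio=dict(
            f0_level_shift_hz=0.5,
            f0_range_shift_st=0.2,
            h1_h2_shift_db=-0.8,
            rms_shift_db=0.5,
            amp_sd_shift_db=0.3,
        ),
    )
    null = EffectPreset(
        name="null",
        feature_effects=_effects(),
        audio=dict(
            f0_level_shift_hz=0.0,
            f0_range_shift_st=0.0,
            h1_h2_shift_db=0.0,
            rms_shift_db=0.0,
            amp_sd_shift_db=0.0,
        ),
    )
    return {
        "VBRO": intervention,
        "MEDI": replace(intervention, name="MEDI"),
        "CONT": cont,
        "null": null,
    }


#: Within-speaker session-to-session noise (sd of BEF-AFT diffs under the
#: null), per feature, in native units. Synthetic calibration values.
SESSION_NOISE_SD = {
    "f0_min_hz": 3.0,
    "f0_max_hz": 5.0,
    "f0_range_st": 0.0,  # recomputed from min/max, not drawn
    "f0_sd_hz": 1.5,
    "f0_level_hz": 2.5,
    "n_pauses": 0.0,  # integer-valued, handled separately
    "mean_pause_s": 0.05,
    "speaking_rate_sps": 0.2,
    "rms_level_db": 1.0,
    "rms_sd_db": 0.5,
    "f1_hz": 30.0,
    "f2_hz": 50.0,
    "f3_hz": 60.0,
    "h1_h2_db": 1.0,
    "h1_a1_db": 1.2,
    "h1_a2_db": 1.2,
    "h1_a3_db": 1.2,
    "h1_h2_sd_db": 0.3,
    "h1_a1_sd_db": 0.3,
    "h1_a2_sd_db": 0.3,
    "h1_a3_sd_db": 0.3,
}

#: Relative sd of the per-speaker effect around the arm mean.
EFFECT_HETEROGENEITY = 0.30


@dataclass(frozen=True)
class CohortDesign:
    """Study-design twin: three arms, gender-stratified, paired readings.

    Defaults mirror the emulated study: 10 speakers per arm (7 female,
    3 male), one BEF and one AFT reading each. ``effects`` maps each arm
    to its :class:`EffectPreset` (``preset`` may name a built-in set;
    "directional" uses the per-arm defaults, "null" zeroes every arm).
    """

    n_per_group: int = 10
    n_female_per_group: int = 7
    seed: int = 0
    preset: str = "directional"
    sample_rate: float = 48_000.0
    duration_s: float = 20.0
    effects: dict | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 speakers per group")
        if not 0 <= self.n_female_per_group <= self.n_per_group:
            raise ValueError("invalid gender split")

    def arm_effects(self) -> dict:
        if self.effects is not None:
            return self.effects
        presets = default_effect_presets()
        if self.preset == "directional":
            return {arm: presets[arm] for arm in ("VBRO", "MEDI", "CONT")}
        if self.preset == "null":
            return {arm: presets["null"] for arm in ("VBRO", "MEDI", "CONT")}
        raise ValueError(f"unknown preset {self.preset!r}")

    def speakers(self) -> pd.DataFrame:
        rows = []
        idx = 1
        for arm in ("VBRO", "MEDI", "CONT"):
            for j in range(self.n_per_group):
                gender = "F" if j < self.n_female_per_group else "M"
                rows.append(
                    {"speaker_id": f"S{idx:02d}", "gender": gender, "treatment": arm}
                )
                idx += 1
        return pd.DataFrame(rows)


#: Gender-specific baseline distributions (mean, sd) for the feature-level
#: simulator — conventional phonetics values, synthetic, not study data.
BASELINES = {
    "F": {
        "f0_level_hz": (200.0, 20.0),
        "f0_range_st": (8.0, 1.5),
        "f1_hz": (550.0, 40.0),
        "f2_hz": (1700.0, 90.0),
        "f3_hz": (2800.0, 120.0),
        "h1_h2_db": (6.0, 2.0),
    },
    "M": {
        "f0_level_hz": (120.0, 15.0),
        "f0_range_st": (7.0, 1.5),
        "f1_hz": (500.0, 40.0),
        "f2_hz": (1500.0, 90.0),
        "f3_hz": (2500.0, 120.0),
        "h1_h2_db": (3.0, 2.0),
    },
}


def _draw_baseline(rng: np.random.Generator, gender: str) -> dict:
    g = BASELINES[gender]

    def draw(key):
        mu, sd = g[key]
        return rng.normal(mu, sd)

    level = draw("f0_level_hz")
    range_st = max(3.0, draw("f0_range_st"))
    f0_min = level * 2 ** (-0.55 * range_st / 12.0)
    f0_max = f0_min * 2 ** (range_st / 12.0)
    h1_h2 = float(np.clip(draw("h1_h2_db"), -9.0, 10.5))
    base = {
        "f0_min_hz": f0_min,
        "f0_max_hz": f0_max,
        "f0_range_st": range_st,
        "f0_sd_hz": abs(rng.normal(0.12 * level, 0.03 * level)),
        "f0_level_hz": level,
        "n_pauses": int(rng.integers(2, 5)),
        "mean_pause_s": rng.normal(0.55, 0.08),
        "speaking_rate_sps": rng.normal(4.0, 0.4),
        "rms_level_db": rng.normal(-22.0, 2.0),
        "rms_sd_db": abs(rng.normal(4.0, 0.8)),
        "f1_hz": draw("f1_hz"),
        "f2_hz": draw("f2_hz"),
        "f3_hz": draw("f3_hz"),
        "h1_h2_db": h1_h2,
        "h1_a1_db": h1_h2 + rng.normal(4.0, 2.0),
        "h1_a2_db": h1_h2 + rng.normal(8.0, 2.5),
        "h1_a3_db": h1_h2 + rng.normal(12.0, 2.5),
    }
    for key in ("h1_h2_sd_db", "h1_a1_sd_db", "h1_a2_sd_db", "h1_a3_sd_db"):
        base[key] = abs(rng.normal(1.5, 0.4))
    return base


def simulate_cohort_features(design: CohortDesign) -> pd.DataFrame:
    """Draw paired BEF/AFT feature tables without synthesising audio.

    Per speaker, a gender-specific baseline vector is drawn, the arm's
    effect (plus 30% per-speaker heterogeneity) and session noise are
    subtracted to give AFT, and the f0 range is recomputed from the
    simulated minimum and maximum so every row is internally consistent.
    The output schema matches the extractor's batch CSV plus ``gender``
    and ``treatment`` columns. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    arm_effects = design.arm_effects()
    rows = []
    for spk in design.speakers().itertuples():
        effects = arm_effects[spk.treatment].feature_effects
        bef = _draw_baseline(rng, spk.gender)
        aft = {}
        for key in FEATURE_COLUMNS:
            if key == "f0_range_st":
                continue
            eff = effects.get(key, 0.0)
            eff = eff + rng.normal(0.0, EFFECT_HETEROGENEITY * abs(eff))
            if key == "n_pauses":
                aft[key] = max(0, int(bef[key] + rng.integers(-1, 2)))
                continue
            noise = rng.normal(0.0, SESSION_NOISE_SD[key])
            aft[key] = bef[key] - eff + noise
        for cond, vec in (("BEF", bef), ("AFT", aft)):
            vec = dict(vec)
            vec["f0_min_hz"] = max(vec["f0_min_hz"], 40.0)
            vec["f0_max_hz"] = max(vec["f0_max_hz"], vec["f0_min_hz"] * 1.05)
            vec["f0_range_st"] = 12.0 * math.log2(vec["f0_max_hz"] / vec["f0_min_hz"])
            rows.append(
                {
                    "speaker_id": spk.speaker_id,
                    "gender": spk.gender,
                    "treatment": spk.treatment,
                    "condition": cond,
                    **{k: vec[k] for k in FEATURE_COLUMNS},
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort_audio(design: CohortDesign, out_dir) -> tuple:
    """Synthesise a full audio cohort: WAVs, manifest, ground truth.

    Writes two WAV files per speaker (conditions BEF and AFT) embodying
    the drawn baseline and the arm's audio-realisable effects, a
    manifest CSV in the ingestion format, and a ground-truth table with
    every programmed quantity. Returns ``(manifest, truth_table)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)
    arm_effects = design.arm_effects()

    manifest_rows, truth_rows = [], []
    for spk in design.speakers().itertuples():
        g = BASELINES[spk.gender]
        level = rng.normal(*g["f0_level_hz"])
        range_st = float(np.clip(rng.normal(*g["f0_range_st"]), 4.0, 12.0))
        h1_h2 = float(np.clip(rng.normal(*g["h1_h2_db"]), -8.0, 10.0))
        formants = tuple(rng.normal(*g[k]) for k in ("f1_hz", "f2_hz", "f3_hz"))
        amp_sd = abs(rng.normal(2.5, 0.4))
        n_pauses = int(rng.integers(2, 5))

        audio_fx = arm_effects[spk.treatment].audio
        het = {
            k: v + rng.normal(0.0, EFFECT_HETEROGENEITY * abs(v))
            for k, v in audio_fx.items()
        }

        # one layout per speaker: the same text is read in both conditions
        layout = build_reading_layout(
            design.duration_s, rng, n_pauses=n_pauses
        )
        per_condition = {
            "BEF": dict(
                f0_level_hz=level, f0_range_st=range_st, h1_h2_db=h1_h2,
                soft_db=0.0, amp_sd_db=amp_sd,
            ),
            "AFT": dict(
                f0_level_hz=level - het["f0_level_shift_hz"],
                f0_range_st=float(
                    np.clip(range_st - het["f0_range_shift_st"], 3.0, 14.0)
                ),
                h1_h2_db=float(np.clip(h1_h2 - het["h1_h2_shift_db"], -10.0, 11.0)),
                soft_db=het["rms_shift_db"],
                amp_sd_db=max(0.5, amp_sd - het["amp_sd_shift_db"]),
            ),
        }
        for cond, params in per_condition.items():
            spec = build_reading_spec(
                duration_s=design.duration_s,
                rng=rng,
                sample_rate=design.sample_rate,
                formants_hz=formants,
                layout=layout,
                **params,
            )
            signal, truth = synthesize_utterance(spec)
            fname = f"{spk.speaker_id}_{cond}.wav"
            write_wav(out_dir / fname, signal, bits=16)
            manifest_rows.append(
                {
                    "speaker_id": spk.speaker_id,
                    "gender": spk.gender,
                    "treatment": spk.treatment,
                    "condition": cond,
                    "path": str(out_dir / fname),
                }
            )
            truth_rows.append(
                {
                    "speaker_id": spk.speaker_id,
                    "gender": spk.gender,
                    "treatment": spk.treatment,
                    "condition": cond,
                    "programmed_rms_shift_db": het["rms_shift_db"]
                    if cond == "AFT"
                    else 0.0,
                    **{
                        f"true_{k}": v
                        for k, v in {
                            "f0_level_hz": truth.f0_level_hz,
                            "f0_min_hz": truth.f0_min_hz,
                            "f0_max_hz": truth.f0_max_hz,
                            "f0_range_st": truth.f0_range_st,
                            "h1_h2_db": truth.h1_h2_db,
                            "f1_hz": truth.formants_hz[0],
                            "f2_hz": truth.formants_hz[1],
                            "f3_hz": truth.formants_hz[2],
                            "n_pauses": truth.n_pauses,
                            "mean_pause_s": truth.mean_pause_s,
                            "n_syllables": truth.n_syllables,
                        }.items()
                    },
                }
            )

    manifest_df = pd.DataFrame(manifest_rows)
    manifest_path = out_dir / "manifest.csv"
    manifest_df.to_csv(manifest_path, index=False)
    truth_df = pd.DataFrame(truth_rows)
    truth_df.to_csv(out_dir / "ground_truth.csv", index=False)
    return CohortManifest(records=manifest_df), truth_df
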