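"""Shared fixtures: synthetic signals and a small audio cohort.

Audio fixtures are synthesised at 16 kHz with shortened readings so the
whole suite stays fast; the generator's design defaults (48 kHz, 20 s,
10 speakers per arm) are exercised separately where cheap.
"""

import numpy as np
import pytest

from prosodiff import (
    AudioSignal,
    CohortDesign,
    extract_features,
    peak_normalise,
    simulate_cohort_audio,
    within_speaker_differences,
)

RATE = 16_000.0


def make_sine(freq_hz: float, amp: float, duration_s: float = 1.0,
              rate: float = RATE) -> AudioSignal:
    t = np.arange(int(duration_s * rate)) / rate
    return AudioSignal(amp * np.sin(2 * np.pi * freq_hz * t), rate)


def make_noise(duration_s: float, rate: float = RATE, amp: float = 0.5,
               seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return amp * rng.uniform(-1, 1, int(duration_s * rate))


def make_glide(f_start: float, f_end: float, duration_s: float = 2.0,
               rate: float = RATE) -> AudioSignal:
    """Harmonic-rich linear f0 glide (fundamental + half-amp octave)."""
    t = np.arange(int(duration_s * rate)) / rate
    phase = 2 * np.pi * (f_start * t + (f_end - f_start) * t**2 / (2 * duration_s))
    x = 0.6 * np.sin(phase) + 0.3 * np.sin(2 * phase)
    return AudioSignal(x, rate)


@pytest.fixture(scope="session")
def audio_cohort(tmp_path_factory):
    """Small synthetic audio cohort: 3 speakers/arm, 10 s readings."""
    out = tmp_path_factory.mktemp("cohort")
    design = CohortDesign(
        n_per_group=3, n_female_per_group=2, seed=11,
        sample_rate=RATE, duration_s=10.0,
    )
    manifest, truth = simulate_cohort_audio(design, out)
    return design, manifest, truth


@pytest.fixture(scope="session")
def cohort_features(audio_cohort):
    _, manifest, _ = audio_cohort
    return extract_features(manifest)


@pytest.fixture(scope="session")
def cohort_diffs(cohort_features):
    return within_speaker_differences(cohort_features)
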