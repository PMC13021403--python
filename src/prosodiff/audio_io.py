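"""Audio and cohort-manifest I/O, amplitude normalisation, and framing.

All DSP stages share the conventions fixed here: times are seconds,
intervals are half-open ``[start, end)``, sample index 0 corresponds to
time 0.0, and amplitudes are real numbers in full-scale units ``[-1, 1]``.
Only uncompressed PCM (and IEEE-float) WAV is accepted; compressed or
otherwise exotic containers are rejected so that provenance of the signal
stays explicit.
"""

from __future__ import annotations

import struct
import wave
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioSignal",
    "CohortManifest",
    "FrameSeries",
    "AudioFormatError",
    "ManifestError",
    "TREATMENTS",
    "CONDITIONS",
    "GENDERS",
    "read_wav",
    "write_wav",
    "peak_normalise",
    "frame_signal",
    "load_manifest",
]

TREATMENTS = ("VBRO", "MEDI", "CONT")
CONDITIONS = ("BEF", "AFT")
GENDERS = ("F", "M")


class AudioFormatError(ValueError):
    """Raised when an audio file cannot be interpreted as plain PCM."""


class ManifestError(ValueError):
    """Raised when a cohort manifest violates the study-design schema."""


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled waveform in full-scale units.

    Parameters
    ----------
    samples
        Float amplitudes, nominally within ``[-1, 1]``.
    rate
        Sampling rate in Hz.
    source_id
        Opaque label (typically the originating file name).
    """

    samples: np.ndarray
    rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise AudioFormatError("AudioSignal requires a 1-D sample array")
        if samples.size < 1:
            raise AudioFormatError("empty signal")
        if not self.rate > 0:
            raise AudioFormatError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.rate

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def scaled(self, gain: float) -> "AudioSignal":
        """Return a copy with every sample multiplied by ``gain``."""
        return replace(self, samples=self.samples * gain)


@dataclass(frozen=True)
class FrameSeries:
    """Uniform analysis frames tiling a signal left to right.

    Frames are half-open windows ``[t, t + frame_length)``; the last
    partial frame is dropped.
    """

    frame_start_times: np.ndarray
    frame_length: float
    hop: float
    frames: np.ndarray  # shape (n_frames, samples_per_frame)
    rate: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def centre_times(self) -> np.ndarray:
        return self.frame_start_times + self.frame_length / 2.0


@dataclass(frozen=True)
class CohortManifest:
    """Validated speaker/condition/treatment table for a cohort.

    Each row is one recording: ``(speaker_id, gender, treatment,
    condition, path)``. A speaker appears under exactly one treatment and
    each ``(speaker_id, condition)`` pair is unique.
    """

    records: pd.DataFrame = field(repr=False)

    COLUMNS = ("speaker_id", "gender", "treatment", "condition", "path")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise ManifestError("no records")
        bad_treat = df.loc[~df["treatment"].isin(TREATMENTS)]
        if len(bad_treat):
            raise ManifestError(
                f"unknown treatment label(s) in rows {bad_treat.index.tolist()}: "
                f"{sorted(bad_treat['treatment'].unique())}"
            )
        bad_cond = df.loc[~df["condition"].isin(CONDITIONS)]
        if len(bad_cond):
            raise ManifestError(
                f"unknown condition label(s) in rows {bad_cond.index.tolist()}: "
                f"{sorted(bad_cond['condition'].unique())}"
            )
        bad_gender = df.loc[~df["gender"].isin(GENDERS)]
        if len(bad_gender):
            raise ManifestError(
                f"unknown gender label(s) in rows {bad_gender.index.tolist()}: "
                f"{sorted(bad_gender['gender'].unique())}"
            )
        dupes = df.duplicated(subset=["speaker_id", "condition"])
        if dupes.any():
            raise ManifestError(
                f"duplicate (speaker_id, condition) pairs in rows "
                f"{df.index[dupes].tolist()}"
            )
        multi = df.groupby("speaker_id")["treatment"].nunique()
        offenders = multi[multi > 1].index.tolist()
        if offenders:
            raise ManifestError(
                f"speaker(s) listed under more than one treatment: {offenders}"
            )

    @property
    def speakers(self) -> list:
        return sorted(self.records["speaker_id"].unique().tolist())

    @property
    def n_speakers(self) -> int:
        return self.records["speaker_id"].nunique()

    def to_csv(self, path) -> None:
        self.records.loc[:, list(self.COLUMNS)].to_csv(path, index=False)


def _decode_pcm(data: np.ndarray) -> np.ndarray:
    """Scale integer PCM samples to float full-scale [-1, 1]."""
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        return (data.astype(np.float64) - 128.0) / 128.0
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float64) / 2147483648.0
    if data.dtype in (np.float32, np.float64):
        return data.astype(np.float64)
    raise AudioFormatError(f"unsupported WAV sample format: {data.dtype}")


def read_wav(path) -> AudioSignal:
    """Read a PCM WAV file into a mono full-scale :class:`AudioSignal`.

    Stereo files are averaged to mono. Integer samples are scaled by the
    full-scale value of their bit depth; 24-bit PCM is handled via the
    container's 32-bit representation.

    Raises
    ------
    AudioFormatError
        For compressed/non-PCM audio, an empty data chunk, or more than
        two channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, struct.error, EOFError) as exc:
        raise AudioFormatError(f"{path.name}: not plain PCM WAV ({exc})") from exc
    data = np.atleast_1d(data)
    if data.size == 0:
        raise AudioFormatError(f"{path.name}: empty signal")
    if data.ndim == 2:
        if data.shape[1] > 2:
            raise AudioFormatError(
                f"{path.name}: {data.shape[1]} channels, expected mono or stereo"
            )
        samples = _decode_pcm(data).mean(axis=1)
    else:
        samples = _decode_pcm(data)
    return AudioSignal(samples=samples, rate=float(rate), source_id=path.name)


def write_wav(path, signal: AudioSignal, bits: int = 16) -> None:
    """Write an :class:`AudioSignal` as 16- or 24-bit PCM WAV.

    Samples are clipped to [-1, 1] before quantisation.
    """
    if bits not in (16, 24):
        raise AudioFormatError(f"unsupported output bit depth: {bits}")
    clipped = np.clip(signal.samples, -1.0, 1.0)
    full_scale = float(2 ** (bits - 1) - 1)
    quantised = np.round(clipped * full_scale).astype(np.int64)
    with wave.open(str(path), "wb") as handle:
        handle.setnchannels(1)
        handle.setsampwidth(bits // 8)
        handle.setframerate(int(round(signal.rate)))
        if bits == 16:
            raw = quantised.astype("<i2").tobytes()
        else:  # pack int32 little-endian, drop the high byte -> 3-byte PCM
            raw = quantised.astype("<i4").tobytes()
            buf = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)
            raw = buf[:, :3].tobytes()
        handle.writeframes(raw)


def peak_normalise(signal: AudioSignal, target_fraction: float = 0.99) -> AudioSignal:
    """Scale a signal so its absolute peak equals ``target_fraction``.

    A pure gain: the waveform shape is unchanged. Applying the operation
    twice is identical to applying it once.
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError(f"target_fraction must be in (0, 1], got {target_fraction}")
    peak = float(np.max(np.abs(signal.samples)))
    if peak == 0.0:
        raise ValueError("silent input, cannot normalise")
    return signal.scaled(target_fraction / peak)


def frame_signal(signal: AudioSignal, frame_length: float, hop: float) -> FrameSeries:
    """Cut a signal into uniform, possibly overlapping frames.

    The frame count follows ``floor((duration - frame_length)/hop) + 1``;
    any trailing partial frame is dropped.
    """
    if hop <= 0:
        raise ValueError(f"hop must be positive, got {hop}")
    if frame_length < hop:
        raise ValueError("frame_length must be >= hop")
    n_len = int(round(frame_length * signal.rate))
    n_hop = int(round(hop * signal.rate))
    if n_len > signal.n_samples:
        raise ValueError(
            f"frame length {frame_length:.3f}s exceeds signal duration "
            f"{signal.duration:.3f}s"
        )
    n_frames = (signal.n_samples - n_len) // n_hop + 1
    idx = np.arange(n_len)[None, :] + n_hop * np.arange(n_frames)[:, None]
    return FrameSeries(
        frame_start_times=np.arange(n_frames) * n_hop / signal.rate,
        frame_length=n_len / signal.rate,
        hop=n_hop / signal.rate,
        frames=signal.samples[idx],
        rate=signal.rate,
    )


def load_manifest(path) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    Expected header: ``speaker_id,gender,treatment,condition,path``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    except pd.errors.EmptyDataError as exc:
        raise ManifestError("no records") from exc
    for col in ("gender", "treatment", "condition"):
        if col in df.columns:
            df[col] = df[col].str.strip().str.upper()
    if "speaker_id" in df.columns:
        df["speaker_id"] = df["speaker_id"].str.strip()
    return CohortManifest(records=df)
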