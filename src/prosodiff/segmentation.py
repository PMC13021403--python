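"""Silent-pause segmentation, pause statistics and speaking rate.

Pauses are detected from short-time intensity relative to the utterance's
peak intensity, so the segmentation is invariant to global gain. Leading
and trailing room silence is labelled ``pause`` but excluded from pause
statistics: only internal pauses (flanked by speech on both sides) count.

Defaults — 25 dB threshold below peak, 0.25 s minimum pause, 0.10 s
minimum speech run — are conventional values for read speech and are all
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .audio_io import AudioSignal, frame_signal

__all__ = [
    "SegmentTrack",
    "PauseStats",
    "intensity_contour",
    "detect_pauses",
    "pause_stats",
    "count_syllable_nuclei",
    "speaking_rate",
]

# Intensity framing used for segmentation and nucleus detection. The 20 ms
# window is reserved for the RMS loudness measures, so segmentation uses a
# slightly longer 30 ms window at the common 10 ms hop.
INTENSITY_WINDOW_S = 0.030
INTENSITY_HOP_S = 0.010

SPEECH = "speech"
PAUSE = "pause"


@dataclass(frozen=True)
class SegmentTrack:
    """Alternating speech/pause intervals covering ``[0, total_duration)``."""

    intervals: tuple  # of (start_s, end_s, label)
    total_duration: float
    warning: str | None = None

    def __post_init__(self) -> None:
        prev_end = 0.0
        prev_label = None
        for start, end, label in self.intervals:
            if label not in (SPEECH, PAUSE):
                raise ValueError(f"unknown segment label {label!r}")
            if not math.isclose(start, prev_end, abs_tol=1e-9):
                raise ValueError("intervals must be contiguous")
            if end <= start:
                raise ValueError("intervals must have positive duration")
            if label == prev_label:
                raise ValueError("labels must alternate")
            prev_end = end
            prev_label = label
        if self.intervals and not math.isclose(
            prev_end, self.total_duration, rel_tol=0, abs_tol=1e-6
        ):
            raise ValueError("intervals must cover the full duration")

    @property
    def speech_intervals(self) -> list:
        return [(s, e) for s, e, lab in self.intervals if lab == SPEECH]

    @property
    def internal_pauses(self) -> list:
        """Pause intervals flanked by speech on both sides."""
        out = []
        for i, (s, e, lab) in enumerate(self.intervals):
            if lab == PAUSE and 0 < i < len(self.intervals) - 1:
                out.append((s, e))
        return out

    @property
    def total_speech_time(self) -> float:
        return float(sum(e - s for s, e in self.speech_intervals))

    @property
    def speech_span(self) -> float:
        """Duration from first to last speech interval (pauses included)."""
        speech = self.speech_intervals
        if not speech:
            return 0.0
        return speech[-1][1] - speech[0][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.intervals), columns=["start_s", "end_s", "label"]
        )

    def to_file(self, path, sep: str = "\t") -> None:
        """Write intervals as delimited text (start, end, label)."""
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_file(cls, path, sep: str = "\t") -> "SegmentTrack":
        df = pd.read_csv(path, sep=sep)
        intervals = tuple(
            (float(r.start_s), float(r.end_s), str(r.label)) for r in df.itertuples()
        )
        return cls(intervals=intervals, total_duration=intervals[-1][1])


@dataclass(frozen=True)
class PauseStats:
    """Count and mean duration of internal silent pauses.

    ``mean_pause_s`` is NaN (undefined), never zero, when no internal
    pause exists.
    """

    n_pauses: int
    mean_pause_s: float
    total_speech_time: float


def intensity_contour(
    signal: AudioSignal,
    window_s: float = INTENSITY_WINDOW_S,
    hop_s: float = INTENSITY_HOP_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Short-time RMS intensity in dB (re full scale).

    Returns ``(centre_times, intensity_db)``; silent frames map to -inf.
    """
    frames = frame_signal(signal, window_s, hop_s)
    rms = np.sqrt(np.mean(frames.frames**2, axis=1))
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(rms)
    return frames.centre_times, db


def detect_pauses(
    signal: AudioSignal,
    silence_threshold_db: float = 25.0,
    min_pause_s: float = 0.25,
    min_speech_s: float = 0.10,
) -> SegmentTrack:
    """Partition an utterance into speech and silent-pause intervals.

    A frame is silent when its intensity falls more than
    ``silence_threshold_db`` below the utterance's peak frame intensity.
    Silent runs shorter than ``min_pause_s`` are absorbed into speech;
    speech runs shorter than ``min_speech_s`` are merged into the
    neighbouring pauses. The threshold is relative to the peak, so the
    segmentation is unchanged by any global gain g > 0.
    """
    if silence_threshold_db <= 0 or min_pause_s <= 0 or min_speech_s <= 0:
        raise ValueError("thresholds must be positive")
    duration = signal.duration
    if duration < INTENSITY_WINDOW_S:
        raise ValueError("signal shorter than one intensity window")
    win, hop = INTENSITY_WINDOW_S, INTENSITY_HOP_S

    def all_silent() -> SegmentTrack:
        return SegmentTrack(
            intervals=((0.0, duration, PAUSE),),
            total_duration=duration,
            warning="all-silent signal",
        )

    centres, db = intensity_contour(signal)
    peak_db = float(np.max(db))
    if not np.isfinite(peak_db):
        return all_silent()
    silent = db < (peak_db - silence_threshold_db)
    n = silent.size

    # Silent runs become pause *spans* covering the union of their
    # windows [j*hop, j*hop + win): boundaries are recovered at hop
    # resolution without the window-length bias a slot labelling incurs.
    spans = []
    j = 0
    while j < n:
        if silent[j]:
            k = j
            while k < n and silent[k]:
                k += 1
            start = 0.0 if j == 0 else j * hop
            end = duration if k == n else min((k - 1) * hop + win, duration)
            if not spans or start > spans[-1][1]:
                spans.append([start, end])
            else:  # overlapping spans (speech gap shorter than a window)
                spans[-1][1] = end
            j = k
        else:
            j += 1

    # Keep internal spans of at least min_pause_s; leading/trailing
    # silence is labelled pause under the same length rule.
    eps = 1e-9
    pauses = [
        (s, e) for s, e in spans
        if (e - s) >= min_pause_s or (s <= eps and e >= duration - eps)
    ]
    if pauses and pauses[0][0] <= eps and pauses[0][1] >= duration - eps:
        return all_silent()

    # Alternate with speech; speech gaps shorter than min_speech_s are
    # merged into the surrounding pause.
    merged = []
    for s, e in pauses:
        if merged and s - merged[-1][1] < min_speech_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    if merged and merged[0][0] < min_speech_s and merged[0][0] > 0:
        merged[0][0] = 0.0  # opening sliver of speech joins the lead pause
    if merged and duration - merged[-1][1] < min_speech_s and merged[-1][1] < duration:
        merged[-1][1] = duration

    intervals = []
    cursor = 0.0
    for s, e in merged:
        if s > cursor:
            intervals.append((cursor, s, SPEECH))
        intervals.append((max(s, cursor), e, PAUSE))
        cursor = e
    if cursor < duration:
        intervals.append((cursor, duration, SPEECH))
    if not intervals:
        intervals = [(0.0, duration, SPEECH)]
    if all(lab == PAUSE for _, _, lab in intervals):
        return all_silent()
    return SegmentTrack(intervals=tuple(intervals), total_duration=duration)


def pause_stats(track: SegmentTrack) -> PauseStats:
    """Count internal pauses and their mean duration.

    Leading/trailing silence never counts; with zero internal pauses the
    mean is NaN.
    """
    pauses = track.internal_pauses
    durations = [e - s for s, e in pauses]
    return PauseStats(
        n_pauses=len(pauses),
        mean_pause_s=float(np.mean(durations)) if durations else math.nan,
        total_speech_time=track.total_speech_time,
    )


def count_syllable_nuclei(
    signal: AudioSignal,
    track: SegmentTrack,
    voiced_mask: np.ndarray,
    mask_times: np.ndarray | None = None,
    dip_db: float = 2.0,
    min_separation_s: float = 0.10,
) -> int:
    """Count syllable nuclei as voiced intensity peaks inside speech.

    A nucleus is a local maximum of the intensity contour that (a) lies in
    a speech interval, (b) is voiced, (c) rises at least ``dip_db`` above
    the surrounding dips (peak prominence), and (d) is at least
    ``min_separation_s`` from the previous nucleus.

    ``voiced_mask`` is a boolean array over analysis frames; if its grid
    differs from the 10 ms intensity grid, pass the frame centre times as
    ``mask_times`` and the mask is resampled by nearest neighbour.
    """
    times, db = intensity_contour(signal)
    finite = np.isfinite(db)
    floor = db[finite].min() if finite.any() else 0.0
    db = np.where(finite, db, floor)

    voiced_mask = np.asarray(voiced_mask, dtype=bool)
    if voiced_mask.size != times.size:
        if mask_times is None:
            raise ValueError(
                "voiced_mask length differs from intensity frames; "
                "provide mask_times for alignment"
            )
        idx = np.clip(
            np.searchsorted(mask_times, times), 0, voiced_mask.size - 1
        )
        voiced = voiced_mask[idx]
    else:
        voiced = voiced_mask

    min_dist = max(1, int(round(min_separation_s / INTENSITY_HOP_S)))
    peaks, _ = find_peaks(db, prominence=dip_db, distance=min_dist)

    speech = track.speech_intervals
    count = 0
    for p in peaks:
        t = times[p]
        if not voiced[p]:
            continue
        if any(s <= t < e for s, e in speech):
            count += 1
    return count


def speaking_rate(
    n_syllables: int, track: SegmentTrack, include_pauses: bool = True
) -> float:
    """Syllables per second over the utterance.

    The default denominator is the span from the first to the last speech
    interval (internal pauses included); ``include_pauses=False`` gives
    the articulation-rate variant (speech time only).
    """
    if n_syllables < 0:
        raise ValueError("n_syllables must be non-negative")
    denom = track.speech_span if include_pauses else track.total_speech_time
    if denom <= 0:
        raise ValueError("zero utterance duration, speaking rate undefined")
    return n_syllables / denom
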