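"""Signal conditioning: rescaling, 32 ms framing, per-frame standardization,
and device-changeover day stitching.

The conditioning chain mirrors how the device data are prepared for the
frame classifiers: each recording is uniformly rescaled into (-1, 1) by one
global gain, split into non-overlapping 256-sample frames, and each frame is
standardized to zero mean and unit variance.  No randomness anywhere in this
module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import FRAME_SAMPLES, FRAME_SECONDS, SAMPLE_RATE, AudioRecording

_RESCALE_EPS = 1e-12


@dataclass
class PreprocessConfig:
    frame_ms: float = 32.0
    target_range: tuple = (-1.0, 1.0)
    tail_policy: str = "drop"  # trailing partial frame
    zero_variance_policy: str = "zero"  # constant frames -> all-zero, flagged

    def __post_init__(self) -> None:
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")

    @property
    def frame_samples(self) -> int:
        return int(round(self.frame_ms * SAMPLE_RATE / 1000.0))


@dataclass
class FrameSet:
    """Ordered fixed-length frames aligned to a timeline.

    ``frames`` is (n_frames, 256); ``start_times`` gives each frame's start in
    seconds from the recording start; ``zero_variance`` flags frames that were
    constant before standardization.
    """

    frames: np.ndarray
    start_times: np.ndarray
    normalized: bool = False
    zero_variance: np.ndarray = None
    log_energy: np.ndarray = None  # pre-standardization log10 frame power

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64).reshape(-1, FRAME_SAMPLES)
        self.start_times = np.asarray(self.start_times, dtype=np.float64)
        if self.start_times.size != self.frames.shape[0]:
            raise ValueError("start_times must have one entry per frame")
        if self.zero_variance is None:
            self.zero_variance = np.zeros(self.frames.shape[0], dtype=bool)

    def __len__(self) -> int:
        return self.frames.shape[0]


def rescale(recording: AudioRecording) -> AudioRecording:
    """Uniformly rescale one recording into (-1, 1) by its peak magnitude.

    One global gain per recording preserves within-recording dynamics (the
    level contrast between wearer and distant speech).  All-zero recordings
    are returned unchanged; the operation is idempotent up to epsilon.
    """
    x = recording.samples
    if x.size == 0:
        raise ValueError("cannot rescale an empty recording")
    peak = np.max(np.abs(x))
    if peak == 0.0:
        return recording
    scaled = x / (peak + _RESCALE_EPS)
    return AudioRecording(
        samples=scaled,
        participant_id=recording.participant_id,
        day_index=recording.day_index,
        session_id=recording.session_id,
        start_minute_of_day=recording.start_minute_of_day,
    )


def frame(recording: AudioRecording, config: PreprocessConfig | None = None) -> FrameSet:
    """Split into consecutive non-overlapping 32 ms frames; drop the tail."""
    config = config or PreprocessConfig()
    step = config.frame_samples
    x = recording.samples
    n_frames = x.size // step
    if n_frames == 0:
        warnings.warn("recording shorter than one frame; empty FrameSet", stacklevel=2)
        return FrameSet(np.empty((0, step)), np.empty(0))
    frames = x[: n_frames * step].reshape(n_frames, step)
    starts = np.arange(n_frames) * (step / SAMPLE_RATE)
    return FrameSet(frames.copy(), starts)


def normalize_frames(frameset: FrameSet) -> FrameSet:
    """Standardize each frame independently to zero mean, unit variance.

    Sample variance (ddof=1) is used.  Zero-variance frames carry no
    waveform information; they are mapped to all-zeros and flagged.  The
    pre-standardization log frame power is kept on the FrameSet: absolute
    level is erased from the waveform by this step, and level relative to the
    surrounding frames is the physical proximity cue the wearer/other
    classifier feeds on.
    """
    f = frameset.frames
    if f.shape[0] == 0:
        return FrameSet(f, frameset.start_times, normalized=True)
    log_e = np.log10(np.mean(f**2, axis=1) + 1e-12)
    mean = f.mean(axis=1, keepdims=True)
    sd = f.std(axis=1, ddof=1, keepdims=True)
    # constant frames detected exactly (std of a constant is only ~0 in floats)
    flat = np.ptp(f, axis=1) == 0.0
    sd[flat] = 1.0
    out = (f - mean) / sd
    out[flat] = 0.0
    return FrameSet(out, frameset.start_times, normalized=True, zero_variance=flat, log_energy=log_e)


def preprocess(recording: AudioRecording, config: PreprocessConfig | None = None) -> FrameSet:
    """rescale -> frame -> normalize, the full conditioning chain."""
    return normalize_frames(frame(rescale(recording), config))


@dataclass
class DayTimeline:
    """One calendar day of a participant's recording, in minute slots.

    ``segments`` is a list of (session_id, start_minute_of_day, n_minutes)
    sorted by start minute; a stitched changeover day simply holds the two
    device sessions back to back on the same clock.
    """

    day_index: int
    segments: list = field(default_factory=list)
    minutes_per_day: int = 1440

    def covered_minutes(self) -> np.ndarray:
        out = []
        for _, start, n in self.segments:
            out.append(np.arange(start, start + n))
        return np.concatenate(out) if out else np.empty(0, dtype=int)


def stitch_days(sessions, n_days: int = 7, minutes_per_day: int = 1440) -> list:
    """Assemble per-day timelines, merging device-changeover partial days.

    ``sessions`` are objects with ``day_index``, ``start_minute_of_day``,
    ``session_id`` and ``duration_s``.  Two sessions on the same calendar day
    (the battery-swap day) are concatenated by clock time into one day.
    Overlapping clock intervals on the same day are an error; minutes are
    never double counted.
    """
    by_day: dict[int, list] = {}
    for s in sessions:
        by_day.setdefault(s.day_index, []).append(s)

    timelines = []
    for day in range(n_days):
        tl = DayTimeline(day_index=day, minutes_per_day=minutes_per_day)
        occupied = np.zeros(minutes_per_day, dtype=bool)
        for s in sorted(by_day.get(day, []), key=lambda s: s.start_minute_of_day):
            n_min = int(np.ceil(s.duration_s / 60.0))
            start = s.start_minute_of_day
            if start + n_min > minutes_per_day:
                raise ValueError(f"session {s.session_id} runs past the end of day {day}")
            span = slice(start, start + n_min)
            if occupied[span].any():
                raise ValueError(f"overlapping sessions on day {day} at minute {start}")
            occupied[span] = True
            tl.segments.append((s.session_id, start, n_min))
        timelines.append(tl)
    return timelines
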