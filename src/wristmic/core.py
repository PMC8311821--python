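"""Shared constants and containers for the wrist-microphone audio pipeline.

The device contract throughout the package: mono audio at 8 kHz, analysed in
non-overlapping 32 ms frames (256 samples).  Frame truth uses a four-way
label set; "speech" for the occupancy measure means live human speech
(wearer or bystander), while device-generated speech (TV/radio) counts as
non-speech.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SAMPLE_RATE: int = 8000
FRAME_SAMPLES: int = 256
FRAME_SECONDS: float = FRAME_SAMPLES / SAMPLE_RATE  # 0.032 s

# Label codes are ordered by precedence: when events overlap inside a frame,
# the higher code wins the majority vote tie-break.
NONSPEECH = 0
DEVICE_SPEECH = 1
OTHER_SPEECH = 2
WEARER_SPEECH = 3

LABEL_NAMES = {
    NONSPEECH: "nonspeech",
    DEVICE_SPEECH: "device_speech",
    OTHER_SPEECH: "other_speech",
    WEARER_SPEECH: "wearer_speech",
}
LABEL_CODES = {name: code for code, name in LABEL_NAMES.items()}


def is_live_speech(labels: np.ndarray) -> np.ndarray:
    """Boolean mask of frames containing live human speech (wearer or other)."""
    labels = np.asarray(labels)
    return labels >= OTHER_SPEECH


@dataclass
class AudioRecording:
    """One contiguous mono recording at the device sample rate.

    ``day_index`` and ``start_minute_of_day`` place the recording on the
    participant's clock so minute-level aggregation can bin it by time of day.
    """

    samples: np.ndarray
    sample_rate: int = SAMPLE_RATE
    participant_id: str = ""
    day_index: int = 0
    session_id: str = ""
    start_minute_of_day: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("recording must be mono (1-D samples)")
        if self.sample_rate != SAMPLE_RATE:
            raise ValueError(f"sample_rate must be {SAMPLE_RATE} Hz, got {self.sample_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def n_frames(self) -> int:
        return self.samples.size // FRAME_SAMPLES


@dataclass
class FrameTruth:
    """Per-frame ground-truth class labels aligned to 32 ms framing."""

    labels: np.ndarray  # int codes, one per frame
    frame_seconds: float = FRAME_SECONDS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        bad = ~np.isin(self.labels, list(LABEL_NAMES))
        if bad.any():
            raise ValueError(f"unknown label codes: {np.unique(self.labels[bad])}")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def speech_mask(self) -> np.ndarray:
        return is_live_speech(self.labels)

    def class_counts(self) -> dict:
        return {LABEL_NAMES[c]: int(np.sum(self.labels == c)) for c in LABEL_NAMES}
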