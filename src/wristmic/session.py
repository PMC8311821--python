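"""Session timelines: event lists rendered to audio plus frame-level truth.

A session is a timeline of acoustic events (wearer speech, other live
speech, device-generated speech, non-speech backgrounds) over a noise
floor.  Rendering mixes the events into one waveform and derives one truth
label per 32 ms frame by majority occupancy, with precedence
wearer > other > device > nonspeech when events overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEVICE_SPEECH,
    FRAME_SAMPLES,
    NONSPEECH,
    OTHER_SPEECH,
    SAMPLE_RATE,
    WEARER_SPEECH,
    AudioRecording,
    FrameTruth,
    LABEL_CODES,
)
from .synth import VoiceSpec, _as_rng, synthesize_background, synthesize_speech_segment

# Proximity defaults: the wearer's mouth is ~30 cm from the wrist microphone,
# so wearer speech arrives louder and drier than bystander speech.
WEARER_LEVEL_DB = 12.0
WEARER_REVERB = 0.1
OTHER_LEVEL_DB = 0.0
OTHER_REVERB = 0.5
DEVICE_LEVEL_DB = 3.0


@dataclass(frozen=True)
class Event:
    """One acoustic event on the session timeline."""

    klass: str  # wearer_speech | other_speech | device_speech | nonspeech
    start_s: float
    end_s: float
    voice: VoiceSpec | None = None
    background_kind: str = "ambient"  # for klass == nonspeech

    def __post_init__(self) -> None:
        if self.klass not in LABEL_CODES:
            raise ValueError(f"unknown event class {self.klass!r}")
        if self.end_s <= self.start_s:
            raise ValueError("event must have positive duration")
        if self.start_s < 0:
            raise ValueError("event starts before the session")

    @property
    def code(self) -> int:
        return LABEL_CODES[self.klass]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SessionSpec:
    duration_s: float
    events: list = field(default_factory=list)
    noise_floor_db: float = -20.0
    seed: int = 0
    participant_id: str = ""
    day_index: int = 0
    session_id: str = ""
    start_minute_of_day: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for ev in self.events:
            if ev.end_s > self.duration_s + 1e-9:
                raise ValueError(f"event {ev} extends past the session end")


def _default_voice(code: int, rng) -> VoiceSpec:
    from .synth import random_voice

    if code == WEARER_SPEECH:
        return random_voice(rng, level_db=WEARER_LEVEL_DB, reverb_amount=WEARER_REVERB)
    return random_voice(rng, level_db=OTHER_LEVEL_DB, reverb_amount=OTHER_REVERB)


def paint_sample_labels(events, n_samples: int) -> np.ndarray:
    """Per-sample truth labels, painting classes in increasing precedence."""
    labels = np.full(n_samples, NONSPEECH, dtype=np.int8)
    for code in (DEVICE_SPEECH, OTHER_SPEECH, WEARER_SPEECH):
        for ev in events:
            if ev.code != code:
                continue
            i0 = max(0, int(round(ev.start_s * SAMPLE_RATE)))
            i1 = min(n_samples, int(round(ev.end_s * SAMPLE_RATE)))
            labels[i0:i1] = code
    return labels


def frame_majority_labels(sample_labels: np.ndarray) -> np.ndarray:
    """Collapse per-sample labels to one label per complete 256-sample frame.

    The label is the class occupying the most samples in the frame; ties go
    to the higher-precedence class.
    """
    n_frames = sample_labels.size // FRAME_SAMPLES
    if n_frames == 0:
        return np.empty(0, dtype=np.int8)
    grid = sample_labels[: n_frames * FRAME_SAMPLES].reshape(n_frames, FRAME_SAMPLES)
    counts = np.stack([(grid == c).sum(axis=1) for c in (WEARER_SPEECH, OTHER_SPEECH, DEVICE_SPEECH, NONSPEECH)])
    order = np.array([WEARER_SPEECH, OTHER_SPEECH, DEVICE_SPEECH, NONSPEECH], dtype=np.int8)
    return order[np.argmax(counts, axis=0)]


def session_truth(spec: SessionSpec) -> FrameTruth:
    """Frame truth for a session without rendering any audio (cheap path)."""
    n = int(round(spec.duration_s * SAMPLE_RATE))
    return FrameTruth(frame_majority_labels(paint_sample_labels(spec.events, n)))


def render_session(spec: SessionSpec) -> tuple[AudioRecording, FrameTruth]:
    """Mix all events over the noise floor and emit aligned frame truth.

    Deterministic given the spec (including its seed).  Events without an
    explicit voice get class-default proximity parameters (wearer loud/dry,
    other speakers quieter/reverberant).
    """
    rng = _as_rng(np.random.SeedSequence(spec.seed))
    n = int(round(spec.duration_s * SAMPLE_RATE))
    x = synthesize_background(spec.duration_s, "broadband_noise", rng, level_db=spec.noise_floor_db)

    for ev in spec.events:
        i0 = max(0, int(round(ev.start_s * SAMPLE_RATE)))
        i1 = min(n, int(round(ev.end_s * SAMPLE_RATE)))
        if i1 <= i0:
            continue
        dur = (i1 - i0) / SAMPLE_RATE
        if ev.code in (WEARER_SPEECH, OTHER_SPEECH):
            voice = ev.voice or _default_voice(ev.code, rng)
            seg = synthesize_speech_segment(dur, voice, rng)
        elif ev.code == DEVICE_SPEECH:
            seg = synthesize_background(dur, "device_speech", rng, level_db=DEVICE_LEVEL_DB, voice=ev.voice)
        else:
            seg = synthesize_background(dur, ev.background_kind, rng, level_db=spec.noise_floor_db + 6.0)
        x[i0:i1] += seg

    rec = AudioRecording(
        samples=x,
        participant_id=spec.participant_id,
        day_index=spec.day_index,
        session_id=spec.session_id,
        start_minute_of_day=spec.start_minute_of_day,
    )
    truth = FrameTruth(frame_majority_labels(paint_sample_labels(spec.events, n)))
    return rec, truth
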