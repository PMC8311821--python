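"""Packaged annotated training corpus: a pilot-recording stand-in.

The trained models need an annotated, multi-session corpus recorded across
varied settings.  Real pilot recordings of that kind cannot be shipped, so
this module synthesizes one: each session has its own wearer voice, its own
cast of bystander voices and device (TV/radio) voice, and its own mix of
quiet, ambient-noise, live-speech and device-speech material.  Sessions are
the cross-validation unit, so voices never recur across sessions — a
held-out session is always an unseen speaker.

Default scale is 15 sessions of 2 minutes (30 min total): large enough for
stable frame counts per class, small enough to train per-fold models on one
CPU in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import AnnotatedFrames
from .core import AudioRecording, FrameTruth
from .preprocess import PreprocessConfig, frame, normalize_frames, rescale
from .session import Event, SessionSpec, render_session
from .synth import _as_rng, random_voice
from .session import OTHER_LEVEL_DB, OTHER_REVERB, WEARER_LEVEL_DB, WEARER_REVERB

# Event-class weights on the session timeline: live speech about 40% of time,
# device speech a strong hard-negative presence, the rest background.
_CLASS_WEIGHTS = {
    "wearer_speech": 0.20,
    "other_speech": 0.22,
    "device_speech": 0.18,
    "nonspeech_event": 0.15,  # ambient/broadband textures over the floor
    "silence": 0.25,
}


@dataclass
class CorpusSession:
    session_id: str
    recording: AudioRecording
    truth: FrameTruth


def _session_events(duration_s: float, rng) -> list:
    wearer = random_voice(rng, level_db=WEARER_LEVEL_DB, reverb_amount=WEARER_REVERB)
    others = [random_voice(rng, level_db=OTHER_LEVEL_DB, reverb_amount=OTHER_REVERB) for _ in range(3)]
    device = random_voice(rng, level_db=0.0, reverb_amount=0.0)

    names = list(_CLASS_WEIGHTS)
    weights = np.array([_CLASS_WEIGHTS[k] for k in names])
    weights = weights / weights.sum()

    events, t = [], 0.0
    while t < duration_s - 1.0:
        klass = rng.choice(names, p=weights)
        dur = float(rng.uniform(2.0, 8.0))
        end = min(t + dur, duration_s)
        if klass == "wearer_speech":
            events.append(Event("wearer_speech", t, end, voice=wearer))
        elif klass == "other_speech":
            events.append(Event("other_speech", t, end, voice=others[rng.integers(len(others))]))
        elif klass == "device_speech":
            events.append(Event("device_speech", t, end, voice=device))
        elif klass == "nonspeech_event":
            kind = "ambient" if rng.random() < 0.6 else "broadband_noise"
            events.append(Event("nonspeech", t, end, background_kind=kind))
        # "silence": nothing over the noise floor
        t = end + float(rng.uniform(0.2, 1.5))
    return events


def build_training_corpus(
    seed: int = 0,
    n_sessions: int = 15,
    session_s: float = 120.0,
    noise_floor_db: float = -20.0,
) -> list:
    """Synthesize the fixed annotated corpus used to train and evaluate models.

    ``noise_floor_db`` sets the session noise floor relative to the bystander
    speech level; raising it lowers the corpus SNR.
    """
    root = np.random.SeedSequence(seed)
    sessions = []
    for i, ss in enumerate(root.spawn(n_sessions)):
        rng = _as_rng(ss)
        spec = SessionSpec(
            duration_s=session_s,
            events=_session_events(session_s, rng),
            noise_floor_db=noise_floor_db,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            session_id=f"session_{i:02d}",
        )
        rec, truth = render_session(spec)
        rec.session_id = spec.session_id
        sessions.append(CorpusSession(spec.session_id, rec, truth))
    return sessions


def prepare_annotated(sessions, config: PreprocessConfig | None = None) -> list:
    """Run the conditioning chain on each session, keeping truth aligned."""
    out = []
    for s in sessions:
        fs = normalize_frames(frame(rescale(s.recording), config))
        labels = s.truth.labels[: len(fs)]
        out.append(AnnotatedFrames(s.session_id, fs, labels))
    return out
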