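"""File formats: WAV audio, frame-truth CSV, manifests, tables.

Audio is written as 16-bit PCM mono WAV at 8 kHz.  Frame truth travels as
CSV (frame_index, start_time_s, label); cohort and run manifests as JSON.
By default only probabilities and aggregate tables are exported from a run —
raw audio stays inside the pipeline unless explicitly requested.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import FRAME_SECONDS, LABEL_CODES, LABEL_NAMES, SAMPLE_RATE, AudioRecording, FrameTruth


def write_wav(path, recording: AudioRecording) -> None:
    """16-bit PCM mono at 8 kHz; samples are clipped to (-1, 1) first."""
    x = np.clip(recording.samples, -1.0, 1.0)
    wavfile.write(str(path), SAMPLE_RATE, (x * 32767.0).astype(np.int16))


def read_wav(path, **identity) -> AudioRecording:
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError("only mono WAV is accepted")
    if rate != SAMPLE_RATE:
        raise ValueError(f"expected {SAMPLE_RATE} Hz audio, got {rate} Hz")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    else:
        samples = data.astype(np.float64)
    return AudioRecording(samples=samples, sample_rate=rate, **identity)


def write_frame_truth(path, truth: FrameTruth) -> None:
    idx = np.arange(len(truth))
    pd.DataFrame(
        {
            "frame_index": idx,
            "start_time_s": idx * FRAME_SECONDS,
            "label": [LABEL_NAMES[c] for c in truth.labels],
        }
    ).to_csv(path, index=False)


def read_frame_truth(path) -> FrameTruth:
    df = pd.read_csv(path)
    return FrameTruth(np.array([LABEL_CODES[l] for l in df["label"]], dtype=np.int8))


def write_probabilities(path, session_id: str, probs: np.ndarray) -> None:
    pd.DataFrame(
        {"session_id": session_id, "frame_index": np.arange(probs.size), "probability": probs}
    ).to_csv(path, index=False, float_format="%.6f")


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_profiles(path, profiles: pd.DataFrame) -> None:
    profiles.to_csv(path, index=False, float_format="%.6f")
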