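"""End-to-end detection and aggregation over a cohort.

For each rendered minute: condition the audio, score every frame with the
speech model, call the minute (mean frame probability > 0.5), and — inside
speech minutes only — score the frames the speech model flagged with the
wearer model.  Unrendered silent minutes enter the day tables as non-speech.
An oracle mode feeds ground-truth labels through the identical aggregation
path, isolating the measurement chain from classifier error.

Raw waveforms never leave this module: outputs are per-minute probabilities
and per-participant summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aggregate import (
    SPEECH_THRESHOLD,
    minute_speech_calls,
    participant_profile,
)
from .classify import OracleClassifier, predict_speech_prob, predict_wearer_prob
from .cohort import Cohort, Participant
from .core import WEARER_SPEECH, is_live_speech
from .preprocess import preprocess


def _minute_probs(minute, speech_model, oracle: bool):
    """Frame speech probabilities for one rendered minute (+ its FrameSet)."""
    if oracle:
        return is_live_speech(minute.truth.labels).astype(float), None
    if minute.recording is None:
        raise ValueError("cohort was generated without audio; use oracle mode")
    fs = preprocess(minute.recording)
    return predict_speech_prob(speech_model, fs), fs


def _wearer_counts(minute, fs, p1, wearer_model, oracle: bool, threshold: float):
    """(n_speech_frames, n_wearer_frames) for one speech-called minute."""
    idx = np.flatnonzero(p1 > threshold)
    if idx.size == 0:
        return 0, 0
    if oracle:
        p2 = (minute.truth.labels[idx] == WEARER_SPEECH).astype(float)
    else:
        p2 = predict_wearer_prob(wearer_model, fs, idx)
    return int(idx.size), int(np.sum(p2 > threshold))


def analyze_participant(
    participant: Participant,
    speech_model=None,
    wearer_model=None,
    oracle: bool = False,
    threshold: float = SPEECH_THRESHOLD,
    expected_days: int = 7,
):
    """Run detection + aggregation for one participant; group label untouched.

    With ``wearer_model=None`` (and not oracle) the wearer measure is left
    missing and only the occupancy measures are computed.
    """
    if not oracle and speech_model is None:
        raise ValueError("need a trained speech model unless oracle=True")
    day_calls = []
    wearer_rows = []
    for day in participant.days:
        probs, minutes_idx, per_minute = [], [], {}
        for m in day.minutes:
            p1, fs = _minute_probs(m, speech_model, oracle)
            probs.append(p1)
            minutes_idx.append(np.full(p1.size, m.sim_minute))
            per_minute[m.sim_minute] = (m, fs, p1)
        frame_probs = np.concatenate(probs) if probs else np.empty(0)
        frame_minute = np.concatenate(minutes_idx).astype(int) if minutes_idx else np.empty(0, int)
        calls = minute_speech_calls(
            frame_probs,
            frame_minute,
            minute_of_day=day.minute_of_day_map(),
            n_minutes=day.minutes_per_day,
            threshold=threshold,
        )
        day_calls.append(calls)
        if not oracle and wearer_model is None:
            continue
        for sim_minute in calls.loc[calls["is_speech"], "minute"]:
            m, fs, p1 = per_minute[int(sim_minute)]
            n_speech, n_wearer = _wearer_counts(m, fs, p1, wearer_model, oracle, threshold)
            if n_speech:
                wearer_rows.append(
                    {
                        "day": day.day_index,
                        "minute": int(sim_minute),
                        "n_speech_frames": n_speech,
                        "n_wearer_frames": n_wearer,
                    }
                )
    wearer_counts = pd.DataFrame(wearer_rows, columns=["day", "minute", "n_speech_frames", "n_wearer_frames"])
    return participant_profile(
        day_calls,
        wearer_counts,
        participant_id=participant.participant_id,
        group=participant.group,
        expected_days=expected_days,
    )


def analyze_cohort(
    cohort: Cohort,
    speech_model=None,
    wearer_model=None,
    oracle: bool = False,
    threshold: float = SPEECH_THRESHOLD,
) -> pd.DataFrame:
    """Participant profile table for a whole cohort."""
    rows = [
        analyze_participant(
            p,
            speech_model=speech_model,
            wearer_model=wearer_model,
            oracle=oracle,
            threshold=threshold,
            expected_days=cohort.config.days,
        ).as_row()
        for p in cohort.participants
    ]
    return pd.DataFrame(rows)


def run_study(
    config,
    speech_model=None,
    wearer_model=None,
    oracle: bool = False,
    threshold: float = SPEECH_THRESHOLD,
):
    """Generate a cohort and analyze it participant by participant.

    Streaming counterpart of ``generate_cohort`` + ``analyze_cohort``: each
    participant's rendered audio is dropped as soon as their profile and
    ground truth are extracted, so memory stays flat at any cohort size.
    Returns (estimated profile table, ground-truth table).
    """
    from .cohort import iter_participants, truth_summary

    est_rows, truth_rows = [], []
    for p in iter_participants(config):
        est_rows.append(
            analyze_participant(
                p,
                speech_model=speech_model,
                wearer_model=wearer_model,
                oracle=oracle,
                threshold=threshold,
                expected_days=config.days,
            ).as_row()
        )
        t = truth_summary(p)
        truth_rows.append(
            {
                "participant_id": t.participant_id,
                "group": t.group,
                "speech_pct": t.speech_pct,
                "morning_pct": t.bin_pct["morning"],
                "afternoon_pct": t.bin_pct["afternoon"],
                "evening_pct": t.bin_pct["evening"],
                "wearer_pct": t.wearer_minute_avg_pct,
            }
        )
    return pd.DataFrame(est_rows), pd.DataFrame(truth_rows)
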