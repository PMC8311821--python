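"""From frame probabilities to behavioural speech measures.

The measurement chain: a minute contains speech if the mean frame
probability over that minute exceeds 0.5 (strictly); a day's speech
percentage divides speech minutes by the full epoch (1440 for 24 h) whether
or not every minute was recorded; time-of-day percentages do the same within
morning (6 am-12 pm), afternoon (12 pm-6 pm) and evening (6 pm-12 am) bins;
the wearer measure is the per-minute percentage of speech frames attributed
to the wearer, averaged unweighted across all speech minutes.

Desk-scale days (fewer simulated minutes mapped proportionally onto the
24-h clock) are supported by deriving every denominator from the minute
table itself rather than hard-coding 1440/360.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPEECH_THRESHOLD = 0.5  # strict: a minute is speech iff mean prob > 0.5

# Minute-of-day bin edges, half-open: [360, 720) morning, [720, 1080)
# afternoon, [1080, 1440) evening; 00:00-06:00 is outside all bins but stays
# in the 24-h denominator.
TIME_BINS = {"morning": (360, 720), "afternoon": (720, 1080), "evening": (1080, 1440)}


def minute_speech_calls(
    frame_probs: np.ndarray,
    frame_minute: np.ndarray,
    minute_of_day: dict | None = None,
    n_minutes: int | None = None,
    threshold: float = SPEECH_THRESHOLD,
) -> pd.DataFrame:
    """Collapse frame probabilities to one call per minute.

    ``frame_minute`` assigns each frame to a simulated-minute index.  Minutes
    in ``range(n_minutes)`` with no frames get ``is_speech=False`` and
    ``n_frames=0`` (unrecorded time counts as non-speech).  ``minute_of_day``
    optionally maps simulated minute -> clock minute (0-1439).
    """
    frame_probs = np.asarray(frame_probs, dtype=float)
    frame_minute = np.asarray(frame_minute, dtype=int)
    if frame_probs.size != frame_minute.size:
        raise ValueError("frame_probs and frame_minute must align")
    if n_minutes is None:
        n_minutes = int(frame_minute.max()) + 1 if frame_minute.size else 0

    n_frames = np.bincount(frame_minute, minlength=n_minutes).astype(int)
    prob_sum = np.bincount(frame_minute, weights=frame_probs, minlength=n_minutes)
    with np.errstate(invalid="ignore"):
        mean_prob = np.where(n_frames > 0, prob_sum / np.maximum(n_frames, 1), np.nan)
    is_speech = np.where(n_frames > 0, mean_prob > threshold, False).astype(bool)

    calls = pd.DataFrame(
        {
            "minute": np.arange(n_minutes),
            "n_frames": n_frames,
            "mean_prob": mean_prob,
            "is_speech": is_speech,
        }
    )
    if minute_of_day is not None:
        mod = np.asarray([minute_of_day[m] for m in range(n_minutes)], dtype=int)
    else:
        mod = calls["minute"].to_numpy()
    calls["minute_of_day"] = mod
    return calls


def daily_speech_percent(calls: pd.DataFrame, epoch_minutes: int | None = None) -> float:
    """100 x speech minutes / epoch minutes for one day."""
    if epoch_minutes is None:
        epoch_minutes = len(calls)
    if epoch_minutes <= 0:
        raise ValueError("epoch_minutes must be positive")
    return 100.0 * float(calls["is_speech"].sum()) / epoch_minutes


def time_of_day_percent(calls: pd.DataFrame) -> dict:
    """Per-bin speech percentages for one day.

    The denominator of each bin is the number of the day's minutes whose
    clock time falls in the bin (360 at full scale), so the definition
    carries over unchanged to proportionally compressed days.  The calls
    table must cover the whole epoch (unrecorded minutes included as
    non-speech rows).
    """
    out = {}
    mod = calls["minute_of_day"].to_numpy()
    for name, (lo, hi) in TIME_BINS.items():
        in_bin = (mod >= lo) & (mod < hi)
        denom = int(in_bin.sum())
        speech = int(calls.loc[in_bin, "is_speech"].sum())
        out[name] = 100.0 * speech / denom if denom else float("nan")
    return out


def wearer_minute_percentages(speech_counts: pd.DataFrame) -> np.ndarray:
    """Per-speech-minute wearer percentage: 100 x wearer frames / speech frames."""
    n_speech = speech_counts["n_speech_frames"].to_numpy(dtype=float)
    n_wearer = speech_counts["n_wearer_frames"].to_numpy(dtype=float)
    if np.any(n_wearer > n_speech):
        raise ValueError("wearer frames cannot exceed speech frames in a minute")
    if np.any(n_speech <= 0):
        raise ValueError("speech minutes must contain speech frames")
    return 100.0 * n_wearer / n_speech


def wearer_fraction(speech_counts: pd.DataFrame) -> float:
    """Participant wearer measure: unweighted mean of per-minute percentages
    across all speech minutes (all days pooled).  NaN when the participant
    has no speech minutes (reported as missing, not zero).
    """
    if len(speech_counts) == 0:
        return float("nan")
    return float(np.mean(wearer_minute_percentages(speech_counts)))


@dataclass
class ParticipantSpeechProfile:
    """Behavioural speech summary for one participant."""

    participant_id: str
    group: str = ""
    daily_pct: list = field(default_factory=list)
    speech_pct: float = float("nan")  # mean of daily percentages
    morning_pct: float = float("nan")
    afternoon_pct: float = float("nan")
    evening_pct: float = float("nan")
    wearer_pct: float = float("nan")
    n_days: int = 0
    complete: bool = True

    def as_row(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "group": self.group,
            "speech_pct": self.speech_pct,
            "morning_pct": self.morning_pct,
            "afternoon_pct": self.afternoon_pct,
            "evening_pct": self.evening_pct,
            "wearer_pct": self.wearer_pct,
            "n_days": self.n_days,
            "complete": self.complete,
        }


def participant_profile(
    day_calls: list,
    wearer_counts: pd.DataFrame | None = None,
    participant_id: str = "",
    group: str = "",
    expected_days: int = 7,
) -> ParticipantSpeechProfile:
    """Average daily and per-bin percentages over the recorded days.

    ``day_calls`` holds one minute-call table per day.  With fewer than
    ``expected_days`` days the profile is computed over what exists and
    flagged incomplete.
    """
    if not day_calls:
        raise ValueError("no days provided")
    daily = [daily_speech_percent(c) for c in day_calls]
    bins = [time_of_day_percent(c) for c in day_calls]
    profile = ParticipantSpeechProfile(
        participant_id=participant_id,
        group=group,
        daily_pct=daily,
        speech_pct=float(np.mean(daily)),
        morning_pct=float(np.mean([b["morning"] for b in bins])),
        afternoon_pct=float(np.mean([b["afternoon"] for b in bins])),
        evening_pct=float(np.mean([b["evening"] for b in bins])),
        n_days=len(day_calls),
        complete=len(day_calls) >= expected_days,
    )
    if wearer_counts is not None:
        profile.wearer_pct = wearer_fraction(wearer_counts)
    return profile
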