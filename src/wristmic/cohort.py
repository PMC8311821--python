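"""Synthetic acoustic cohorts: two groups wearing the device for several days.

Each participant gets a fixed wearer voice and a per-participant speech
occupancy (fraction of minutes containing live speech) drawn from their
group's distribution, truncated to [0, 1].  Speech minutes are placed over
the day according to a diurnal weight profile, filled with wearer/other
utterances (the wearer's share of utterances follows the participant's
wearer fraction), and rendered minute by minute.  Device (TV/radio) speech
appears in a share of the otherwise silent minutes.

Days can be compressed for desk-scale runs: ``minutes_per_day`` simulated
minutes are mapped proportionally onto the 1440-minute clock, and only
minutes containing events plus a small sample of silent minutes are actually
rendered; the remaining silent minutes are bookkept as non-speech.  Ground
truth (exact frame counting) is attached to every participant so recovery of
the configured occupancy and wearer fractions can be tested end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FrameTruth, WEARER_SPEECH, is_live_speech
from .session import Event, SessionSpec, render_session, session_truth
from .session import OTHER_LEVEL_DB, OTHER_REVERB, WEARER_LEVEL_DB, WEARER_REVERB
from .synth import _as_rng, random_voice

MINUTE_S = 60.0
CLOCK_MINUTES = 1440


@dataclass(frozen=True)
class GroupSpec:
    """Speech-behaviour distribution of one clinical group.

    Defaults for the two packaged groups live in :func:`default_cohort_config`:
    cases speak/hear speech in 2% (SD 1%) of minutes with 3% (SD 0.3%) of
    speech frames their own; controls 13% (SD 3%) and 11% (SD 1%).
    """

    name: str
    occupancy_mean: float
    occupancy_sd: float
    wearer_mean: float
    wearer_sd: float

    def __post_init__(self) -> None:
        for v in (self.occupancy_mean, self.wearer_mean):
            if not 0.0 <= v <= 1.0:
                raise ValueError("occupancy and wearer fractions must be in [0, 1]")
        if self.occupancy_sd < 0 or self.wearer_sd < 0:
            raise ValueError("SDs must be non-negative")


@dataclass
class CohortConfig:
    n_per_group: int = 29
    days: int = 7
    minutes_per_day: int = 1440
    groups: tuple = ()
    diurnal_weights: tuple = (1.0, 1.0, 1.0)  # morning, afternoon, evening
    night_weight: float = 0.2  # 00:00-06:00, relative to the bin weights
    noise_floor_db: float = -20.0
    speech_coverage: tuple = (0.65, 0.85)  # utterance time per speech minute
    max_silent_rendered: int = 3  # silent minutes rendered per day
    device_minute_rate: float = 0.3  # share of rendered silent minutes with TV
    render_audio: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            self.groups = default_groups()
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if self.days < 1 or self.minutes_per_day < 4:
            raise ValueError("need at least one day of at least 4 minutes")
        if any(w < 0 for w in self.diurnal_weights) or self.night_weight < 0:
            raise ValueError("diurnal weights must be non-negative")
        if sum(self.diurnal_weights) + self.night_weight == 0:
            raise ValueError("at least one diurnal weight must be positive")


def default_groups() -> tuple:
    return (
        GroupSpec("case", occupancy_mean=0.02, occupancy_sd=0.01, wearer_mean=0.03, wearer_sd=0.003),
        GroupSpec("control", occupancy_mean=0.13, occupancy_sd=0.03, wearer_mean=0.11, wearer_sd=0.01),
    )


@dataclass
class MinuteRecord:
    sim_minute: int
    minute_of_day: int
    truth: FrameTruth
    recording: object = None  # AudioRecording when audio is rendered


@dataclass
class ParticipantDay:
    day_index: int
    minutes: list  # rendered MinuteRecords, sorted by sim_minute
    unrendered_minutes: np.ndarray  # sim-minute indices bookkept as silence
    minutes_per_day: int

    def minute_of_day_map(self) -> dict:
        mod = {m.sim_minute: m.minute_of_day for m in self.minutes}
        for sm in self.unrendered_minutes:
            mod[int(sm)] = clock_minute(int(sm), self.minutes_per_day)
        return mod


@dataclass
class Participant:
    participant_id: str
    group: str
    occupancy: float  # drawn per-participant truth parameter
    wearer_frac: float
    days: list = field(default_factory=list)


@dataclass
class Cohort:
    config: CohortConfig
    participants: list = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "seed": self.config.seed,
            "n_per_group": self.config.n_per_group,
            "days": self.config.days,
            "minutes_per_day": self.config.minutes_per_day,
            "groups": [g.name for g in self.config.groups],
            "participants": [
                {"participant_id": p.participant_id, "group": p.group} for p in self.participants
            ],
        }


def clock_minute(sim_minute: int, minutes_per_day: int) -> int:
    """Map a simulated minute onto the 1440-minute clock proportionally."""
    return int(sim_minute * CLOCK_MINUTES // minutes_per_day)


def _minute_weights(minutes_per_day: int, diurnal_weights, night_weight) -> np.ndarray:
    w_morning, w_afternoon, w_evening = diurnal_weights
    mod = np.array([clock_minute(i, minutes_per_day) for i in range(minutes_per_day)])
    w = np.full(minutes_per_day, float(night_weight))
    w[(mod >= 360) & (mod < 720)] = w_morning
    w[(mod >= 720) & (mod < 1080)] = w_afternoon
    w[mod >= 1080] = w_evening
    return w / w.sum()


def _truncated_normal(rng, mean, sd, lo=0.0, hi=1.0):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    from scipy import stats

    if stats.norm.cdf(lo, mean, sd) + stats.norm.sf(hi, mean, sd) > 0.5:
        warnings.warn(
            f"occupancy/wearer distribution N({mean}, {sd}) has most of its mass outside [0, 1]; truncating",
            stacklevel=3,
        )
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _speech_minute_events(rng, wearer_voice, wearer_frac, coverage_range) -> list:
    """Fill one minute with wearer/other utterances to the target coverage."""
    target = rng.uniform(*coverage_range) * MINUTE_S
    events, t, spoken = [], float(rng.uniform(0.0, 2.0)), 0.0
    while spoken < target and t < MINUTE_S - 1.0:
        dur = float(rng.uniform(2.0, 7.0))
        end = min(t + dur, MINUTE_S)
        if rng.random() < wearer_frac:
            events.append(Event("wearer_speech", t, end, voice=wearer_voice))
        else:
            other = random_voice(rng, level_db=OTHER_LEVEL_DB, reverb_amount=OTHER_REVERB)
            events.append(Event("other_speech", t, end, voice=other))
        spoken += end - t
        t = end + float(rng.uniform(0.4, 2.0))
    return events


def _device_minute_events(rng) -> list:
    """A television/radio playing for part of the minute."""
    voice = random_voice(rng, level_db=0.0, reverb_amount=0.0)
    start = float(rng.uniform(0.0, 10.0))
    end = min(start + float(rng.uniform(20.0, 55.0)), MINUTE_S)
    return [Event("device_speech", start, end, voice=voice)]


def generate_participant_day(
    rng, config: CohortConfig, wearer_voice, occupancy: float, wearer_frac: float, day_index: int,
    participant_id: str = "",
) -> ParticipantDay:
    M = config.minutes_per_day
    n_speech = int(round(occupancy * M))
    weights = _minute_weights(M, config.diurnal_weights, config.night_weight)
    speech_minutes = np.sort(rng.choice(M, size=n_speech, replace=False, p=weights))

    silent = np.setdiff1d(np.arange(M), speech_minutes)
    n_extra = min(config.max_silent_rendered, silent.size)
    extra = np.sort(rng.choice(silent, size=n_extra, replace=False)) if n_extra else np.empty(0, int)
    unrendered = np.setdiff1d(silent, extra)

    minutes = []
    for sm in speech_minutes:
        events = _speech_minute_events(rng, wearer_voice, wearer_frac, config.speech_coverage)
        minutes.append(_render_minute(rng, config, events, int(sm), day_index, participant_id))
    for sm in extra:
        events = _device_minute_events(rng) if rng.random() < config.device_minute_rate else []
        minutes.append(_render_minute(rng, config, events, int(sm), day_index, participant_id))
    minutes.sort(key=lambda m: m.sim_minute)
    return ParticipantDay(day_index, minutes, unrendered, M)


def _render_minute(rng, config, events, sim_minute, day_index, participant_id) -> MinuteRecord:
    mod = clock_minute(sim_minute, config.minutes_per_day)
    spec = SessionSpec(
        duration_s=MINUTE_S,
        events=events,
        noise_floor_db=config.noise_floor_db,
        seed=int(rng.integers(2**31)),
        participant_id=participant_id,
        day_index=day_index,
        session_id=f"{participant_id}_d{day_index}_m{sim_minute}",
        start_minute_of_day=mod,
    )
    if config.render_audio:
        rec, truth = render_session(spec)
        return MinuteRecord(sim_minute, mod, truth, rec)
    return MinuteRecord(sim_minute, mod, session_truth(spec))


def iter_participants(config: CohortConfig):
    """Yield participants one at a time (streaming keeps rendered audio for a
    single participant in memory); deterministic given config.seed."""
    root = np.random.SeedSequence(config.seed)
    streams = iter(root.spawn(len(config.groups) * config.n_per_group))
    for group in config.groups:
        for i in range(config.n_per_group):
            rng = _as_rng(next(streams))
            pid = f"{group.name}_{i:02d}"
            wearer_voice = random_voice(rng, level_db=WEARER_LEVEL_DB, reverb_amount=WEARER_REVERB)
            occupancy = _truncated_normal(rng, group.occupancy_mean, group.occupancy_sd)
            wearer_frac = _truncated_normal(rng, group.wearer_mean, group.wearer_sd)
            p = Participant(pid, group.name, occupancy, wearer_frac)
            for d in range(config.days):
                p.days.append(
                    generate_participant_day(rng, config, wearer_voice, occupancy, wearer_frac, d, pid)
                )
            yield p


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full two-group cohort; deterministic given config.seed."""
    config = config or CohortConfig()
    return Cohort(config=config, participants=list(iter_participants(config)))


# ---------------------------------------------------------------------------
# Ground truth summaries (exact counting, independent of the aggregation
# pipeline so oracle-identity tests compare two separately written routes)


@dataclass
class ParticipantTruthProfile:
    participant_id: str
    group: str
    daily_fraction: list  # per-day true speech-minute fraction
    speech_fraction: float  # mean over days
    speech_pct: float  # mean daily percentage (same arithmetic as the pipeline)
    bin_pct: dict  # morning/afternoon/evening true percentages (mean over days)
    wearer_minute_avg_pct: float  # per-minute wearer % averaged over speech minutes
    wearer_frame_fraction: float  # pooled wearer frames / live-speech frames


def _minute_is_speech(labels: np.ndarray) -> bool:
    # a minute counts as a true speech minute when live speech occupies a
    # strict majority of its frames (matching the > 0.5 mean-probability call)
    return int(is_live_speech(labels).sum()) * 2 > labels.size


def truth_summary(participant: Participant) -> ParticipantTruthProfile:
    """Exact speech-occupancy and wearer-fraction truth for one participant.

    Counting is exact; the percentage expressions mirror the aggregation
    pipeline's arithmetic term for term, so an oracle classifier run through
    the pipeline reproduces these values to the last bit.
    """
    if not participant.days:
        raise ValueError("participant has no days")
    daily, daily_pct, bin_days = [], [], []
    minute_pcts = []
    wearer_frames = speech_frames = 0
    for day in participant.days:
        n_speech_minutes = 0
        bin_speech = {"morning": 0, "afternoon": 0, "evening": 0}
        bin_total = {"morning": 0, "afternoon": 0, "evening": 0}
        for m in day.minutes:
            labels = m.truth.labels
            speech_minute = _minute_is_speech(labels)
            n_speech_minutes += speech_minute
            _bin_add(bin_total, m.minute_of_day)
            if speech_minute:
                _bin_add(bin_speech, m.minute_of_day)
                n_sp = int(is_live_speech(labels).sum())
                n_we = int((labels == WEARER_SPEECH).sum())
                minute_pcts.append(100.0 * n_we / n_sp)
                wearer_frames += n_we
                speech_frames += n_sp
        for sm in day.unrendered_minutes:
            _bin_add(bin_total, clock_minute(int(sm), day.minutes_per_day))
        daily.append(n_speech_minutes / day.minutes_per_day)
        daily_pct.append(100.0 * float(n_speech_minutes) / day.minutes_per_day)
        bin_days.append(
            {
                k: (100.0 * bin_speech[k] / bin_total[k]) if bin_total[k] else float("nan")
                for k in bin_total
            }
        )
    return ParticipantTruthProfile(
        participant_id=participant.participant_id,
        group=participant.group,
        daily_fraction=daily,
        speech_fraction=float(np.mean(daily)),
        speech_pct=float(np.mean(daily_pct)),
        bin_pct={k: float(np.mean([b[k] for b in bin_days])) for k in ("morning", "afternoon", "evening")},
        wearer_minute_avg_pct=float(np.mean(minute_pcts)) if minute_pcts else float("nan"),
        wearer_frame_fraction=(wearer_frames / speech_frames) if speech_frames else float("nan"),
    )


def _bin_add(counter: dict, minute_of_day: int) -> None:
    if 360 <= minute_of_day < 720:
        counter["morning"] += 1
    elif 720 <= minute_of_day < 1080:
        counter["afternoon"] += 1
    elif minute_of_day >= 1080:
        counter["evening"] += 1


def truth_table(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for p in cohort.participants:
        t = truth_summary(p)
        rows.append(
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
    return pd.DataFrame(rows)
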