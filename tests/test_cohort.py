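"""Cohort generation: counts, calibration, determinism, truth summaries."""

import numpy as np
import pytest

from wristmic.cohort import (
    CohortConfig,
    GroupSpec,
    clock_minute,
    generate_cohort,
    truth_summary,
    truth_table,
)
from wristmic.core import NONSPEECH, WEARER_SPEECH, FrameTruth
from wristmic.cohort import MinuteRecord, Participant, ParticipantDay


def _fast_cfg(**kw):
    base = dict(n_per_group=2, days=1, minutes_per_day=12, render_audio=False, seed=3)
    base.update(kw)
    return CohortConfig(**base)


class TestGeneration:
    def test_participant_and_day_counts(self):
        cohort = generate_cohort(_fast_cfg(minutes_per_day=10))
        assert len(cohort.participants) == 4  # 2 per group x 2 groups
        for p in cohort.participants:
            assert len(p.days) == 1
            rendered = sum(len(d.minutes) for d in p.days)
            unrendered = sum(d.unrendered_minutes.size for d in p.days)
            assert rendered + unrendered == 10

    def test_degenerate_sd_gives_exact_occupancy(self):
        groups = (
            GroupSpec("case", 0.10, 0.0, 0.5, 0.0),
            GroupSpec("control", 0.10, 0.0, 0.5, 0.0),
        )
        cfg = _fast_cfg(minutes_per_day=100, groups=groups, max_silent_rendered=0)
        cohort = generate_cohort(cfg)
        for p in cohort.participants:
            # SD = 0: exactly round(0.10 * 100) = 10 speech minutes per day
            assert len(p.days[0].minutes) == 10

    def test_deterministic_given_seed(self):
        cfg = _fast_cfg(render_audio=True, minutes_per_day=6)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for pa, pb in zip(a.participants, b.participants):
            for da, db in zip(pa.days, pb.days):
                assert [m.sim_minute for m in da.minutes] == [m.sim_minute for m in db.minutes]
                for ma, mb in zip(da.minutes, db.minutes):
                    assert np.array_equal(ma.truth.labels, mb.truth.labels)
                    assert np.array_equal(ma.recording.samples, mb.recording.samples)

    def test_conservation_per_session(self):
        cohort = generate_cohort(_fast_cfg(render_audio=True, minutes_per_day=6))
        for p in cohort.participants:
            for m in p.days[0].minutes:
                assert sum(m.truth.class_counts().values()) == len(m.truth) == 1875

    def test_infeasible_occupancy_warns(self):
        groups = (GroupSpec("case", 0.0, 0.5, 0.5, 0.0), GroupSpec("control", 0.1, 0.0, 0.5, 0.0))
        with pytest.warns(UserWarning):
            generate_cohort(_fast_cfg(groups=groups))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_per_group=1)
        with pytest.raises(ValueError):
            CohortConfig(diurnal_weights=(1, -1, 1))
        with pytest.raises(ValueError):
            GroupSpec("g", 1.5, 0.1, 0.5, 0.1)


class TestDiurnalPlacement:
    def test_uniform_weights_fill_bins_evenly(self):
        # placement-count oracle at SD = 0: each quarter-day bin holds about
        # the configured occupancy
        groups = (GroupSpec("case", 0.10, 0.0, 0.5, 0.0), GroupSpec("control", 0.10, 0.0, 0.5, 0.0))
        cfg = CohortConfig(
            n_per_group=4, days=3, minutes_per_day=1440, groups=groups,
            diurnal_weights=(1.0, 1.0, 1.0), night_weight=1.0,
            render_audio=False, seed=11, max_silent_rendered=0,
        )
        table = truth_table(generate_cohort(cfg))
        for col in ("morning_pct", "afternoon_pct", "evening_pct"):
            assert table[col].mean() == pytest.approx(10.0, abs=2.0)

    def test_zero_night_weight_puts_no_speech_at_night(self):
        groups = (GroupSpec("case", 0.2, 0.0, 0.5, 0.0), GroupSpec("control", 0.2, 0.0, 0.5, 0.0))
        cfg = _fast_cfg(minutes_per_day=48, groups=groups, night_weight=0.0)
        cohort = generate_cohort(cfg)
        for p in cohort.participants:
            for day in p.days:
                assert all(m.minute_of_day >= 360 for m in day.minutes if _is_speech(m))


def _is_speech(m):
    from wristmic.core import is_live_speech

    return is_live_speech(m.truth.labels).sum() * 2 > len(m.truth)


class TestClockMapping:
    @pytest.mark.parametrize("mpd,sim,expected", [
        (1440, 725, 725),
        (96, 0, 0),
        (96, 24, 360),   # second quarter starts at 06:00
        (96, 95, 1425),
        (48, 12, 360),
    ])
    def test_proportional(self, mpd, sim, expected):
        assert clock_minute(sim, mpd) == expected


class TestTruthSummary:
    def _participant(self, labels_per_minute, minutes_per_day=4):
        minutes = [
            MinuteRecord(i, clock_minute(i, minutes_per_day), FrameTruth(lab))
            for i, lab in enumerate(labels_per_minute)
        ]
        day = ParticipantDay(0, minutes, np.arange(len(labels_per_minute), minutes_per_day), minutes_per_day)
        return Participant("p", "case", 0.5, 0.5, [day])

    def test_all_nonspeech_gives_zero_fraction(self):
        p = self._participant([np.full(1875, NONSPEECH, dtype=np.int8)])
        t = truth_summary(p)
        assert t.speech_fraction == 0.0
        assert np.isnan(t.wearer_minute_avg_pct)

    def test_all_wearer_gives_wearer_fraction_one(self):
        p = self._participant([np.full(1875, WEARER_SPEECH, dtype=np.int8)])
        t = truth_summary(p)
        assert t.wearer_frame_fraction == 1.0
        assert t.wearer_minute_avg_pct == 100.0
        assert t.speech_fraction == pytest.approx(0.25)  # 1 of 4 minutes

    def test_quarter_wearer_fraction(self):
        lab = np.full(100, 2, dtype=np.int8)  # other speech
        lab[:25] = WEARER_SPEECH
        p = self._participant([lab])
        t = truth_summary(p)
        assert t.wearer_frame_fraction == pytest.approx(0.25)

    def test_empty_participant_rejected(self):
        with pytest.raises(ValueError):
            truth_summary(Participant("p", "case", 0.5, 0.5, []))
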