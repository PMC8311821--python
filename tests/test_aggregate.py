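"""Minute calls, daily/time-of-day percentages, wearer fraction, profiles."""

import numpy as np
import pandas as pd
import pytest

from wristmic.aggregate import (
    daily_speech_percent,
    minute_speech_calls,
    participant_profile,
    time_of_day_percent,
    wearer_fraction,
)


def _calls(is_speech, minute_of_day=None):
    n = len(is_speech)
    return pd.DataFrame(
        {
            "minute": np.arange(n),
            "n_frames": np.full(n, 1875),
            "mean_prob": np.where(is_speech, 0.9, 0.1),
            "is_speech": np.asarray(is_speech, dtype=bool),
            "minute_of_day": np.arange(n) if minute_of_day is None else np.asarray(minute_of_day),
        }
    )


class TestMinuteCalls:
    def test_above_threshold_is_speech(self):
        calls = minute_speech_calls(np.full(100, 0.6), np.zeros(100, int))
        assert bool(calls.loc[0, "is_speech"])

    def test_mean_exactly_half_is_not_speech(self):
        # "above 0.5" read strictly
        calls = minute_speech_calls(np.full(10, 0.5), np.zeros(10, int))
        assert calls.loc[0, "mean_prob"] == 0.5
        assert not bool(calls.loc[0, "is_speech"])

    def test_minutes_without_frames_are_nonspeech(self):
        calls = minute_speech_calls(np.full(5, 0.9), np.zeros(5, int), n_minutes=3)
        assert bool(calls.loc[0, "is_speech"])
        assert not calls.loc[1, "is_speech"] and not calls.loc[2, "is_speech"]
        assert calls.loc[1, "n_frames"] == 0

    def test_matches_bruteforce_means(self, rng):
        probs = rng.random(1875 * 5)
        minutes = rng.integers(0, 5, size=probs.size)
        calls = minute_speech_calls(probs, minutes, n_minutes=5)
        for m in range(5):
            sel = probs[minutes == m]
            assert calls.loc[m, "mean_prob"] == pytest.approx(sel.mean())
            assert bool(calls.loc[m, "is_speech"]) == (sel.mean() > 0.5)


class TestDailyPercent:
    def test_144_of_1440_is_ten_percent(self):
        flags = np.zeros(1440, dtype=bool)
        flags[:144] = True
        assert daily_speech_percent(_calls(flags)) == pytest.approx(10.0)

    def test_zero_speech_is_zero(self):
        assert daily_speech_percent(_calls(np.zeros(1440, dtype=bool))) == 0.0

    def test_fixed_epoch_denominator(self):
        flags = np.zeros(720, dtype=bool)  # only half the day recorded
        flags[:72] = True
        assert daily_speech_percent(_calls(flags), epoch_minutes=1440) == pytest.approx(5.0)

    def test_bad_epoch_rejected(self):
        with pytest.raises(ValueError):
            daily_speech_percent(_calls(np.zeros(10, dtype=bool)), epoch_minutes=0)


class TestTimeOfDay:
    def test_morning_only_speech(self):
        flags = np.zeros(1440, dtype=bool)
        flags[360:396] = True  # 36 minutes, all 06:00-06:36
        bins = time_of_day_percent(_calls(flags))
        assert bins["morning"] == pytest.approx(10.0)
        assert bins["afternoon"] == 0.0 and bins["evening"] == 0.0

    def test_uniform_occupancy_fills_each_bin(self, rng):
        p = 0.25
        flags = rng.random(1440) < p
        bins = time_of_day_percent(_calls(flags))
        for v in bins.values():
            assert v == pytest.approx(100 * p, abs=7.0)

    def test_minute_720_counts_as_afternoon(self):
        flags = np.zeros(1440, dtype=bool)
        flags[720] = True
        bins = time_of_day_percent(_calls(flags))
        assert bins["afternoon"] > 0 and bins["morning"] == 0.0

    def test_night_speech_outside_all_bins(self):
        flags = np.zeros(1440, dtype=bool)
        flags[:360] = True  # 00:00-06:00
        bins = time_of_day_percent(_calls(flags))
        assert all(v == 0.0 for v in bins.values())
        assert daily_speech_percent(_calls(flags)) == pytest.approx(25.0)


class TestWearerFraction:
    def test_single_minute(self):
        counts = pd.DataFrame({"n_speech_frames": [1875], "n_wearer_frames": [625]})
        assert wearer_fraction(counts) == pytest.approx(100 * 625 / 1875)

    def test_unweighted_mean_over_minutes(self):
        counts = pd.DataFrame(
            {"n_speech_frames": [100, 1000], "n_wearer_frames": [20, 400]}
        )
        assert wearer_fraction(counts) == pytest.approx(30.0)  # (20% + 40%) / 2

    def test_no_speech_minutes_is_missing(self):
        empty = pd.DataFrame({"n_speech_frames": [], "n_wearer_frames": []})
        assert np.isnan(wearer_fraction(empty))

    def test_order_invariance(self, rng):
        n = rng.integers(50, 500, size=20)
        w = (n * rng.random(20)).astype(int)
        counts = pd.DataFrame({"n_speech_frames": n, "n_wearer_frames": w})
        shuffled = counts.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert wearer_fraction(counts) == pytest.approx(wearer_fraction(shuffled))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            wearer_fraction(pd.DataFrame({"n_speech_frames": [10], "n_wearer_frames": [11]}))


class TestParticipantProfile:
    def test_constant_days_average_to_constant(self):
        days = [_calls(np.r_[np.ones(144, bool), np.zeros(1296, bool)]) for _ in range(7)]
        prof = participant_profile(days)
        assert prof.speech_pct == pytest.approx(10.0)
        assert prof.complete

    def test_one_active_day_averages_down(self):
        # one day at 14%, six at 0% -> 7-day mean of 2%
        quiet = _calls(np.zeros(1000, bool))
        active = np.zeros(1000, dtype=bool)
        active[:140] = True
        prof = participant_profile([_calls(active)] + [quiet] * 6)
        assert prof.speech_pct == pytest.approx(2.0)

    def test_fewer_days_flagged_incomplete(self):
        prof = participant_profile([_calls(np.zeros(1440, bool))] * 5)
        assert not prof.complete and prof.n_days == 5

    def test_bin_means_match_bruteforce(self, rng):
        days = [_calls(rng.random(1440) < 0.2) for _ in range(7)]
        prof = participant_profile(days)
        expected = np.mean([time_of_day_percent(c)["evening"] for c in days])
        assert prof.evening_pct == pytest.approx(expected)

    def test_bin_speech_never_exceeds_total(self, rng):
        days = [_calls(rng.random(1440) < 0.3) for _ in range(3)]
        prof = participant_profile(days)
        total_minutes = sum(c["is_speech"].sum() for c in days)
        bin_minutes = sum(
            c.loc[(c["minute_of_day"] >= 360), "is_speech"].sum() for c in days
        )
        assert bin_minutes <= total_minutes
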