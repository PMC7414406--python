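import datetime as dt

import numpy as np
import pandas as pd
import pytest

from gravitrack.metrics import (IntensityConfig, bout_mask, daily_steps,
                                guideline_compliance, mvpa_minutes,
                                nightly_sleep, percent_change,
                                resting_heart_rate, round_half_away,
                                weekly_and_period_summaries)
from gravitrack.preprocessing import homogenize_heart_rate
from gravitrack.validity import ValidityConfig

DAY = pd.Timestamp("2023-04-01")
SPAN = (DAY, DAY + pd.Timedelta(days=1))
ICFG = IntensityConfig()


def steps_of(pairs):
    if not pairs:
        return pd.Series([], index=pd.DatetimeIndex([]), dtype="int64")
    idx, vals = zip(*pairs)
    return pd.Series(list(vals), index=pd.DatetimeIndex(idx))


class TestDailySteps:
    def test_all_zero_day(self):
        idx = pd.date_range(DAY, periods=1440, freq="min")
        assert daily_steps(pd.Series(0, index=idx), DAY.date()) == 0

    def test_sparse_minutes_sum(self):
        s = steps_of([(DAY + pd.Timedelta(minutes=m), v)
                      for m, v in [(10, 100), (500, 250), (1400, 30)]])
        assert daily_steps(s, DAY.date()) == 380

    def test_other_days_excluded(self):
        s = steps_of([(DAY - pd.Timedelta(minutes=1), 999),
                      (DAY + pd.Timedelta(minutes=3), 7)])
        assert daily_steps(s, DAY.date()) == 7


def audited(rows):
    return pd.DataFrame(rows, columns=["onset", "offset", "awake_minutes",
                                       "status", "reason"])


class TestNightlySleep:
    def test_single_period_with_awake(self):
        sl = audited([(DAY + pd.Timedelta("23:00:00"),
                       DAY + pd.Timedelta(days=1, hours=7), 20.0,
                       "accepted", "")])
        assert nightly_sleep(sl, DAY.date()) == (460.0, 20.0)

    def test_absence_is_missing_not_zero(self):
        assert nightly_sleep(audited([]), DAY.date()) == (None, None)

    def test_two_periods_summed(self):
        sl = audited([
            (DAY + pd.Timedelta("22:00:00"), DAY + pd.Timedelta("27:00:00"),
             0.0, "accepted", ""),
            (DAY + pd.Timedelta("28:00:00"), DAY + pd.Timedelta("31:00:00"),
             0.0, "trimmed", "boundary-movement")])
        assert nightly_sleep(sl, DAY.date()) == (480.0, 0.0)

    def test_attributed_to_onset_night(self):
        sl = audited([(DAY + pd.Timedelta("23:30:00"),
                       DAY + pd.Timedelta(days=1, hours=6), 0.0,
                       "accepted", "")])
        next_day = (DAY + pd.Timedelta(days=1)).date()
        assert nightly_sleep(sl, next_day) == (None, None)
        assert nightly_sleep(sl, DAY.date())[0] == 390.0


def grid_from_bins(bins):
    """bins: list of bpm-or-None, one per 15-min bin from midnight."""
    samples = []
    for i, v in enumerate(bins):
        if v is not None:
            samples.append((DAY + pd.Timedelta(minutes=15 * i + 7), float(v)))
    idx, vals = zip(*samples)
    return homogenize_heart_rate(
        pd.Series(vals, index=pd.DatetimeIndex(idx)),
        max_gap=pd.Timedelta(0), span=SPAN)


class TestRestingHR:
    def test_constant_day(self):
        grid = grid_from_bins([60.0] * 96)
        assert resting_heart_rate(grid, DAY.date()) == 60.0

    def test_two_low_consecutive_bins(self):
        bins = [70.0] * 96
        bins[40], bins[41] = 58.0, 60.0
        assert resting_heart_rate(grid_from_bins(bins), DAY.date()) == 59.0

    def test_all_missing_day(self):
        grid = homogenize_heart_rate(
            pd.Series([], index=pd.DatetimeIndex([]), dtype=float), span=SPAN)
        assert np.isnan(resting_heart_rate(grid, DAY.date()))

    def test_isolated_bin_insufficient(self):
        bins = [None] * 96
        bins[10] = 55.0
        assert np.isnan(resting_heart_rate(grid_from_bins(bins), DAY.date()))

    def test_matches_exhaustive_window_minimum(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            bins = [float(v) if rng.uniform() < 0.7 else None
                    for v in rng.uniform(50, 90, 96)]
            if all(b is None for b in bins):
                continue
            grid = grid_from_bins(bins) if any(b is not None for b in bins) \
                else None
            got = resting_heart_rate(grid, DAY.date())
            best = np.inf
            for i in range(95):
                if bins[i] is not None and bins[i + 1] is not None:
                    best = min(best, (bins[i] + bins[i + 1]) / 2)
            if np.isinf(best):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(best)


class TestBoutRule:
    def test_nine_consecutive_minutes_earn_nothing(self):
        q = np.zeros(60, dtype=bool)
        q[10:19] = True
        assert bout_mask(q, 10).sum() == 0

    def test_ten_consecutive_minutes_earn_ten(self):
        q = np.zeros(60, dtype=bool)
        q[10:20] = True
        assert bout_mask(q, 10).sum() == 10

    def test_split_runs_counted_separately(self):
        q = np.zeros(60, dtype=bool)
        q[0:12] = True
        q[20:33] = True
        assert bout_mask(q, 10).sum() == 25

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            q = rng.uniform(size=rng.integers(1, 200)) < 0.6
            got = bout_mask(q, 10)
            # brute force: scan maximal runs
            expect = np.zeros(len(q), dtype=bool)
            i = 0
            while i < len(q):
                if q[i]:
                    j = i
                    while j < len(q) and q[j]:
                        j += 1
                    if j - i >= 10:
                        expect[i:j] = True
                    i = j
                else:
                    i += 1
            assert (got == expect).all()


class TestMvpaMinutes:
    def test_cadence_fallback_without_hr(self):
        empty_grid = homogenize_heart_rate(
            pd.Series([], index=pd.DatetimeIndex([]), dtype=float), span=SPAN)
        s = steps_of([(DAY + pd.Timedelta(minutes=600 + m), 105)
                      for m in range(12)])
        mod, vig = mvpa_minutes(s, empty_grid, float("nan"), 30.0, ICFG,
                                DAY.date())
        assert (mod, vig) == (12, 0)

    def test_hr_threshold_governs_when_hr_present(self):
        # resting 60, age 30 -> max HR 190, moderate threshold 112
        idx = pd.date_range(DAY, periods=1440, freq="min")
        hr = np.full(1440, 60.0)
        hr[600:615] = 130.0
        grid = homogenize_heart_rate(pd.Series(hr, index=idx), span=SPAN)
        mod, vig = mvpa_minutes(steps_of([]), grid, 60.0, 30.0, ICFG,
                                DAY.date())
        assert mod == 15 and vig == 0

    def test_vigorous_split(self):
        # vigorous threshold = 60 + 0.6*130 = 138
        idx = pd.date_range(DAY, periods=1440, freq="min")
        hr = np.full(1440, 60.0)
        hr[600:630] = 145.0
        grid = homogenize_heart_rate(pd.Series(hr, index=idx), span=SPAN)
        mod, vig = mvpa_minutes(steps_of([]), grid, 60.0, 30.0, ICFG,
                                DAY.date())
        assert vig == 30 and mod == 0


class TestAggregation:
    def make_daily(self, steps_by_day, valid=None):
        rows = []
        for i, v in enumerate(steps_by_day):
            ok = True if valid is None else valid[i]
            rows.append({
                "participant_id": "A", "date": DAY.date(),
                "week_type": "gestational", "week_number": 13 + i // 7,
                "period": "second_trimester", "steps": v,
                "sleep_minutes": 450.0, "awake_minutes": 20.0,
                "resting_hr": 60.0, "mvpa_moderate": 10, "mvpa_vigorous": 0,
                "activity_valid": ok, "sleep_valid": ok,
                "activity_week_valid": True, "sleep_week_valid": True,
            })
        return pd.DataFrame(rows)

    def test_identical_valid_days_give_that_value(self):
        daily = self.make_daily([7000] * 14)
        weekly, period = weekly_and_period_summaries(daily, ValidityConfig())
        assert (weekly["mean_daily_steps"] == 7000).all()
        assert period["steps"].iloc[0] == 7000

    def test_two_valid_days_average(self):
        daily = self.make_daily([6000, 8000, 999],
                                valid=[True, True, False])
        _, period = weekly_and_period_summaries(daily, ValidityConfig())
        assert period["steps"].iloc[0] == 7000

    def test_period_mean_is_concatenated_day_mean(self):
        """No week-weighting: period mean = mean over all valid days."""
        rng = np.random.default_rng(6)
        vals = rng.integers(2000, 12000, 18)
        daily = self.make_daily(list(vals))
        _, period = weekly_and_period_summaries(daily, ValidityConfig())
        assert period["steps"].iloc[0] == pytest.approx(vals.mean())

    def test_period_without_valid_days_absent(self):
        daily = self.make_daily([5000] * 7, valid=[False] * 7)
        _, period = weekly_and_period_summaries(daily, ValidityConfig())
        assert len(period) == 0


def weekly_frame(mod_vig):
    return pd.DataFrame([{
        "participant_id": f"P{i}", "period": "second_trimester",
        "week_type": "gestational", "week_number": 15,
        "activity_week_valid": True,
        "mvpa_moderate_weekly": m, "mvpa_vigorous_weekly": v,
        "mvpa_weekly": m + v} for i, (m, v) in enumerate(mod_vig)])


class TestCompliance:
    def test_moderate_boundary(self):
        out = guideline_compliance(weekly_frame([(150, 0), (149, 0)]), ICFG)
        assert list(out["weekly"]["week_compliant"]) == [True, False]

    def test_vigorous_route(self):
        out = guideline_compliance(weekly_frame([(0, 75), (0, 74)]), ICFG)
        assert list(out["weekly"]["week_compliant"]) == [True, False]

    def test_monotone_in_minutes(self):
        rng = np.random.default_rng(7)
        mods = rng.uniform(0, 200, 50)
        base = guideline_compliance(
            weekly_frame([(m, 0) for m in mods]), ICFG)["weekly"]
        more = guideline_compliance(
            weekly_frame([(m + 30, 0) for m in mods]), ICFG)["weekly"]
        assert (more["week_compliant"] | ~base["week_compliant"]).all()

    def test_reported_proportions(self):
        # 9 of 19 participants -> 47%
        rows = [(160, 0)] * 9 + [(10, 0)] * 10
        out = guideline_compliance(weekly_frame(rows), ICFG)["by_period"]
        assert out["participants_meeting"].iloc[0] == 9
        assert out["participants_pct"].iloc[0] == 47


class TestPercentChange:
    @pytest.mark.parametrize("base, later, expect", [
        (60, 70, 17), (50, 50, 0), (50, 75, 50), (70, 60, -14)])
    def test_examples(self, base, later, expect):
        assert percent_change(base, later) == expect

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(17.5) == 18
        assert round_half_away(-17.5) == -18
        assert round_half_away(100 * 43 / 239) == 18
        assert round_half_away(100 * 9 / 19) == 47
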