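import numpy as np
import pandas as pd
import pytest

from gravitrack.preprocessing import (PROV_AVERAGED, PROV_INTERPOLATED,
                                      PROV_MISSING, cross_check_sleep,
                                      detect_wear, homogenize_heart_rate,
                                      retained_sleep)

DAY = pd.Timestamp("2023-04-01")
SPAN = (DAY, DAY + pd.Timedelta(days=1))


def hr_series(pairs):
    idx, vals = zip(*pairs)
    return pd.Series(list(vals), index=pd.DatetimeIndex(idx), name="bpm")


def sparse_steps(pairs):
    if not pairs:
        return pd.Series([], index=pd.DatetimeIndex([]), dtype="int64",
                         name="steps")
    idx, vals = zip(*pairs)
    return pd.Series(list(vals), index=pd.DatetimeIndex(idx), name="steps")


class TestHomogenize:
    def test_constant_dense_input_all_averaged(self):
        idx = pd.date_range(DAY, periods=1440, freq="min")
        out = homogenize_heart_rate(pd.Series(72.0, index=idx), span=SPAN)
        assert len(out) == 96
        assert (out["provenance"] == PROV_AVERAGED).all()
        assert (out["value"] == 72.0).all()

    def test_two_point_bin_mean(self):
        s = hr_series([(DAY + pd.Timedelta("08:01:00"), 60.0),
                       (DAY + pd.Timedelta("08:11:00"), 70.0)])
        out = homogenize_heart_rate(s, span=SPAN)
        bin_ = out.loc[DAY + pd.Timedelta("08:00:00")]
        assert bin_["value"] == 65.0
        assert bin_["provenance"] == PROV_AVERAGED

    def test_linear_interpolation_between_averaged_bins(self):
        # averaged bins 60 and 76 with 3 empty bins between them
        s = hr_series([(DAY + pd.Timedelta("08:00:00"), 60.0),
                       (DAY + pd.Timedelta("09:00:00"), 76.0)])
        out = homogenize_heart_rate(s, span=SPAN)
        got = out.loc[DAY + pd.Timedelta("08:15:00"):
                      DAY + pd.Timedelta("08:45:00")]
        assert list(got["value"]) == [64.0, 68.0, 72.0]
        assert (got["provenance"] == PROV_INTERPOLATED).all()

    def test_gap_longer_than_max_gap_stays_missing(self):
        s = hr_series([(DAY + pd.Timedelta("08:00:00"), 60.0),
                       (DAY + pd.Timedelta("09:15:00"), 76.0)])
        out = homogenize_heart_rate(s, span=SPAN)
        between = out.loc[DAY + pd.Timedelta("08:15:00"):
                          DAY + pd.Timedelta("09:00:00")]
        assert (between["provenance"] == PROV_MISSING).all()
        assert between["value"].isna().all()

    def test_grid_completeness_regardless_of_sparsity(self):
        s = hr_series([(DAY + pd.Timedelta("12:00:00"), 60.0)])
        out = homogenize_heart_rate(
            s, span=(DAY, DAY + pd.Timedelta(days=3)))
        assert len(out) == 3 * 96
        assert (out.index[1] - out.index[0]) == pd.Timedelta(minutes=15)

    def test_mean_conservation_on_dense_input(self):
        rng = np.random.default_rng(0)
        idx = pd.date_range(DAY, periods=1440, freq="min")
        vals = rng.uniform(55, 100, len(idx))
        out = homogenize_heart_rate(pd.Series(vals, index=idx), span=SPAN)
        per_bin = pd.Series(vals, index=idx).resample("15min").mean()
        assert np.allclose(out["value"], per_bin)
        # uniform sampling: grand bin mean equals the raw-sample mean
        assert out["value"].mean() == pytest.approx(vals.mean())

    def test_unsorted_input_rejected(self):
        s = hr_series([(DAY + pd.Timedelta("08:10:00"), 60.0),
                       (DAY + pd.Timedelta("08:00:00"), 70.0)])
        with pytest.raises(ValueError, match="sorted"):
            homogenize_heart_rate(s, span=SPAN)


class TestDetectWear:
    def test_continuous_hr_coverage_fully_worn(self):
        idx = pd.date_range(DAY, periods=1440, freq="min")
        grid = homogenize_heart_rate(pd.Series(70.0, index=idx), span=SPAN)
        wear = detect_wear(grid, sparse_steps([]), span=SPAN)
        assert wear.all() and len(wear) == 1440

    def test_two_hour_hole_not_worn(self):
        idx = pd.date_range(DAY, periods=1440, freq="min")
        keep = (idx < DAY + pd.Timedelta("10:00:00")) | \
               (idx >= DAY + pd.Timedelta("12:00:00"))
        grid = homogenize_heart_rate(pd.Series(70.0, index=idx[keep]),
                                     span=SPAN, max_gap=pd.Timedelta(0))
        wear = detect_wear(grid, sparse_steps([]), span=SPAN)
        hole = wear[DAY + pd.Timedelta("10:00:00"):
                    DAY + pd.Timedelta("11:59:00")]
        assert (~hole).all() and hole.sum() == 0 and len(hole) == 120

    def test_steps_alone_mark_minute_worn(self):
        wear = detect_wear(
            homogenize_heart_rate(hr_series([(DAY, 70.0)]), span=SPAN),
            sparse_steps([(DAY + pd.Timedelta("13:07:00"), 42)]), span=SPAN)
        assert wear[DAY + pd.Timedelta("13:07:00")]
        assert not wear[DAY + pd.Timedelta("13:08:00")]

    def test_rule_matches_brute_force_minute_evaluation(self):
        rng = np.random.default_rng(1)
        times = pd.DatetimeIndex(sorted(
            DAY + pd.to_timedelta(
                np.unique(rng.integers(0, 86_400, 300)), unit="s")))
        hr = pd.Series(rng.uniform(55, 90, len(times)), index=times)
        step_min = np.unique(rng.integers(0, 1440, 100))
        steps = sparse_steps(
            [(DAY + pd.Timedelta(minutes=int(m)), int(v))
             for m, v in zip(step_min, rng.integers(0, 60, len(step_min)))])
        grid = homogenize_heart_rate(hr, span=SPAN)
        wear = detect_wear(grid, steps, span=SPAN)
        prov = grid["provenance"]
        for m in range(0, 1440, 17):   # sampled minutes, brute force
            ts = DAY + pd.Timedelta(minutes=m)
            bin_start = ts.floor("15min")
            expected = (prov[bin_start] == PROV_AVERAGED) or \
                (steps.get(ts, 0) > 0)
            assert wear[ts] == expected

    def test_adding_hr_never_unwears_a_minute(self):
        rng = np.random.default_rng(2)
        t = sorted(DAY + pd.to_timedelta(
            np.unique(rng.integers(0, 86_400, 50)), unit="s"))
        base = pd.Series(rng.uniform(55, 90, len(t)), index=pd.DatetimeIndex(t))
        grid_a = homogenize_heart_rate(base, span=SPAN)
        wear_a = detect_wear(grid_a, sparse_steps([]), span=SPAN)
        extra_t = sorted(set(t) | set(
            DAY + pd.to_timedelta(np.unique(rng.integers(0, 86_400, 200)),
                                  unit="s")))
        extra = pd.Series(rng.uniform(55, 90, len(extra_t)),
                          index=pd.DatetimeIndex(extra_t))
        wear_b = detect_wear(homogenize_heart_rate(extra, span=SPAN),
                             sparse_steps([]), span=SPAN)
        assert (wear_b | ~wear_a).all()   # worn_a implies worn_b


def full_wear():
    idx = pd.date_range(DAY - pd.Timedelta(days=1), periods=3 * 1440,
                        freq="min")
    return pd.Series(True, index=idx, name="worn")


def sleep_frame(onset, offset, awake=20.0):
    return pd.DataFrame({"onset": [pd.Timestamp(onset)],
                         "offset": [pd.Timestamp(offset)],
                         "awake_minutes": [awake]})


class TestCrossCheckSleep:
    def test_clean_period_accepted_unchanged(self):
        sl = sleep_frame("2023-04-01T23:00:00", "2023-04-02T07:00:00")
        out = cross_check_sleep(sl, sparse_steps([]), full_wear())
        assert list(out["status"]) == ["accepted"]
        assert out.loc[0, "onset"] == sl.loc[0, "onset"]
        assert out.loc[0, "awake_minutes"] == 20.0

    def test_off_wrist_gap_removes_period(self):
        wear = full_wear()
        wear[pd.Timestamp("2023-04-02T03:00:00"):
             pd.Timestamp("2023-04-02T03:29:00")] = False
        sl = sleep_frame("2023-04-01T23:00:00", "2023-04-02T07:00:00")
        out = cross_check_sleep(sl, sparse_steps([]), wear)
        assert list(out["status"]) == ["removed"]
        assert list(out["reason"]) == ["off-wrist"]

    def test_leading_step_run_trimmed(self):
        sl = sleep_frame("2023-04-01T23:00:00", "2023-04-02T07:00:00",
                         awake=48.0)
        steps = sparse_steps([
            (pd.Timestamp("2023-04-01T23:00:00") + pd.Timedelta(minutes=m), 30)
            for m in range(10)])
        out = cross_check_sleep(sl, steps, full_wear())
        assert list(out["status"]) == ["trimmed"]
        assert out.loc[0, "onset"] == pd.Timestamp("2023-04-01T23:10:00")
        assert out.loc[0, "offset"] == pd.Timestamp("2023-04-02T07:00:00")
        # awake minutes rescaled to the retained share of the period
        assert out.loc[0, "awake_minutes"] == pytest.approx(48.0 * 470 / 480)

    def test_high_movement_fraction_removed(self):
        sl = sleep_frame("2023-04-01T23:00:00", "2023-04-02T07:00:00")
        inner = [(pd.Timestamp("2023-04-02T01:00:00")
                  + pd.Timedelta(minutes=2 * m), 25) for m in range(60)]
        out = cross_check_sleep(sl, sparse_steps(inner), full_wear())
        assert list(out["reason"]) == ["movement-mismatch"]

    def test_idempotent_on_its_own_output(self):
        sl = pd.concat([
            sleep_frame("2023-04-01T22:30:00", "2023-04-02T06:30:00"),
            sleep_frame("2023-04-02T23:00:00", "2023-04-03T07:00:00",
                        awake=30.0)], ignore_index=True)
        steps = sparse_steps(
            [(pd.Timestamp("2023-04-01T22:30:00") + pd.Timedelta(minutes=m), 9)
             for m in range(6)])
        once = retained_sleep(cross_check_sleep(sl, steps, full_wear()))
        twice = cross_check_sleep(once[["onset", "offset", "awake_minutes"]],
                                  steps, full_wear())
        assert (twice["status"] == "accepted").all()
        pd.testing.assert_frame_equal(
            once[["onset", "offset", "awake_minutes"]],
            twice[["onset", "offset", "awake_minutes"]])
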