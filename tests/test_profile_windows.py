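import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circact._errors import UndefinedResultWarning, ValidationError
from circact.profile_windows import (
    DiurnalProfile,
    diurnal_minute_profile,
    lflex,
    m10_l5,
    relative_amplitude,
    sliding_window_stat,
)

from conftest import make_minute_series
from oracles import window_scan_bruteforce


def profile_from(values):
    return DiurnalProfile(
        minute_means=np.asarray(values, dtype=float),
        contributing_days=np.ones(1440, dtype=int),
    )


def square_profile(high=100.0, start_h=8, end_h=20):
    p = np.zeros(1440)
    p[start_h * 60 : end_h * 60] = high
    return profile_from(p)


class TestDiurnalProfile:
    def test_identical_days_give_that_day(self, rng):
        day = rng.gamma(2.0, 10.0, size=1440)
        prof = diurnal_minute_profile(make_minute_series(np.tile(day, 3)))
        assert np.allclose(prof.minute_means, day)
        assert np.all(prof.contributing_days == 3)

    def test_two_days_average(self):
        s = make_minute_series(np.concatenate([np.zeros(1440), np.full(1440, 10.0)]))
        prof = diurnal_minute_profile(s)
        assert np.all(prof.minute_means == 5.0)

    def test_single_day_is_identity(self, rng):
        day = rng.gamma(2.0, 10.0, size=1440)
        prof = diurnal_minute_profile(make_minute_series(day))
        assert prof.minute_means.tolist() == day.tolist()

    def test_keyed_by_clock_minute_not_offset(self, rng):
        """A series starting at 06:00 lands its values on the right clock minutes."""
        day = rng.gamma(2.0, 10.0, size=1440)
        shifted = make_minute_series(np.roll(np.tile(day, 2), -360), start="2016-01-04 06:00:00")
        prof = diurnal_minute_profile(shifted)
        assert np.allclose(prof.minute_means, day)


class TestSlidingWindow:
    def test_square_wave_m10_l5_geometry(self):
        prof = square_profile()
        mx = sliding_window_stat(prof, 600, "max")
        assert (mx.level, mx.start_minute, mx.start_time) == (100.0, 480, "08:00")
        mn = sliding_window_stat(prof, 300, "min")
        assert (mn.level, mn.start_minute, mn.start_time) == (0.0, 0, "00:00")

    def test_constant_profile_ties_to_earliest_start(self):
        prof = profile_from(np.full(1440, 7.0))
        for mode in ("min", "max"):
            r = sliding_window_stat(prof, 300, mode)
            assert r.level == 7.0 and r.start_minute == 0

    def test_full_day_window_is_profile_mean(self, rng):
        vals = rng.gamma(2.0, 10.0, size=1440)
        prof = profile_from(vals)
        for mode in ("min", "max"):
            r = sliding_window_stat(prof, 1440, mode)
            assert r.level == pytest.approx(vals.mean())
            assert r.start_minute == 0

    def test_window_wraps_past_midnight(self):
        # quietest 5 h of a square wave active 08:00-20:00 but with the only
        # zero stretch 22:00-03:00: minimum window must cross midnight
        p = np.full(1440, 50.0)
        p[22 * 60 :] = 0.0
        p[: 3 * 60] = 0.0
        r = sliding_window_stat(profile_from(p), 300, "min")
        assert r.level == 0.0 and r.start_minute == 22 * 60

    def test_exactly_1440_candidates(self):
        for length in (1, 300, 600, 1440):
            r = sliding_window_stat(square_profile(), length, "min")
            assert r.n_candidates == 1440

    @pytest.mark.parametrize("length", [0, -5, 1441])
    def test_invalid_length_rejected(self, length):
        with pytest.raises(ValidationError):
            sliding_window_stat(square_profile(), length, "min")

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.integers(min_value=1, max_value=1440),
        st.sampled_from(["min", "max"]),
    )
    def test_matches_naive_scan(self, seed, length, mode):
        vals = np.random.default_rng(seed).gamma(2.0, 10.0, size=1440)
        prof = profile_from(vals)
        got = sliding_window_stat(prof, length, mode)
        level, start = window_scan_bruteforce(vals.tolist(), length, mode)
        assert got.level == pytest.approx(level, rel=1e-9)
        assert got.start_minute == start


class TestM10L5:
    def test_sine_peak_centers_the_windows(self):
        # diurnal sinusoid peaking at 14:00, trough at 02:00
        m = np.arange(1440)
        vals = 50 + 40 * np.cos(2 * np.pi * (m - 14 * 60 + 0.5) / 1440)
        m10, l5 = m10_l5(profile_from(vals))
        assert m10.start_time == "09:00"  # 600-min window centred on 14:00
        assert l5.start_time == "23:30"  # 300-min window centred on 02:00
        assert m10.level >= l5.level

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_m10_above_mean_above_l5(self, seed):
        vals = np.random.default_rng(seed).gamma(2.0, 10.0, size=1440)
        m10, l5 = m10_l5(profile_from(vals))
        assert m10.level >= vals.mean() - 1e-9
        assert l5.level <= vals.mean() + 1e-9
        assert m10.level >= l5.level


class TestLflex:
    def test_450_min_window_in_12h_rest_span(self):
        r = lflex(square_profile(), 450)
        assert r.level == 0.0 and r.start_minute == 0

    def test_300_min_reproduces_l5(self, rng):
        prof = profile_from(rng.gamma(2.0, 10.0, size=1440))
        _, l5 = m10_l5(prof)
        fl = lflex(prof, 300)
        assert (fl.level, fl.start_minute) == (l5.level, l5.start_minute)

    def test_constant_profile(self):
        r = lflex(profile_from(np.full(1440, 3.0)), 120)
        assert r.level == 3.0


class TestRelativeAmplitude:
    @pytest.mark.parametrize(
        "m10,l5,expected", [(100, 0, 1.0), (50, 50, 0.0), (60, 20, 0.5)]
    )
    def test_known_values(self, m10, l5, expected):
        assert relative_amplitude(m10, l5) == pytest.approx(expected)

    def test_zero_total_is_nan_with_warning(self):
        with pytest.warns(UndefinedResultWarning):
            assert np.isnan(relative_amplitude(0.0, 0.0))

    def test_scale_invariant_but_not_shift_invariant(self, rng):
        vals = rng.gamma(2.0, 10.0, size=1440)
        m10, l5 = m10_l5(profile_from(vals))
        base = relative_amplitude(m10.level, l5.level)
        m10s, l5s = m10_l5(profile_from(3.7 * vals))
        assert relative_amplitude(m10s.level, l5s.level) == pytest.approx(base, rel=1e-9)
        m10b, l5b = m10_l5(profile_from(vals + 25.0))
        assert relative_amplitude(m10b.level, l5b.level) != pytest.approx(base, rel=1e-3)
        assert 0.0 <= base <= 1.0
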