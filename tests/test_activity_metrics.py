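"""Volume series, superusers, interposting ECDF, periodogram."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import threadnet as tn
from threadnet.activity_metrics import ActivitySeries, _local_maxima
from threadnet.errors import EmptyInputError, ParameterError
from threadnet.model import Post, PostLog


def _series(counts) -> ActivitySeries:
    counts = np.asarray(counts)
    n_weeks = int(np.ceil(len(counts) / 7))
    return ActivitySeries(
        days=np.arange(len(counts)),
        daily_counts=counts,
        weeks=np.arange(n_weeks),
        weekly_counts=np.zeros(n_weeks),
        weekly_new_users=np.zeros(n_weeks),
        posts_per_user_per_week=np.zeros(n_weeks),
    )


def _log_one_user(days: list[float]) -> PostLog:
    ts = pd.Timestamp("2020-01-01T00:00:00+00:00")
    posts = [Post(f"p{i}", f"t{i}", None, "U", ts + pd.Timedelta(days=d), 1)
             for i, d in enumerate(days)]
    return PostLog(posts=posts)


class TestDailyCounts:
    def test_toy(self, toy_log):
        series = tn.daily_counts(toy_log)
        assert series.daily_counts.tolist() == [1, 1, 1, 1, 1]

    def test_single_day_burst(self):
        log = _log_one_user([0.1, 0.2, 0.3, 0.4])
        series = tn.daily_counts(log)
        assert series.daily_counts.tolist() == [4]

    def test_weekly_conservation(self, toy_log, blf_log):
        for log in (toy_log, blf_log):
            series = tn.daily_counts(log)
            assert series.weekly_counts.sum() == series.total_posts == len(log)

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            tn.daily_counts(PostLog(posts=[]))


class TestSuperusers:
    def test_top_percent_single_member(self, blf_log):
        """1% of ~2000 posting users -> exactly ceil(20) members, the max
        posters first."""
        su = tn.superuser_set(blf_log, "top_percent_posts", 1.0)
        counts = blf_log.posts_per_user()
        assert len(su) == int(np.ceil(0.01 * len(counts)))
        assert su.members[0] == counts.index[0]

    def test_top_n_tie_broken_by_id(self, toy_log):
        su = tn.superuser_set(toy_log, "top_n_posts", 2)
        assert su.members == ["A", "C"]  # A:2, C:2, B:1

    def test_share_monotone_in_percent(self, blf_log):
        shares = [tn.superuser_set(blf_log, "top_percent_posts", p).share_of_posts
                  for p in (1, 2, 5, 10)]
        assert all(b >= a for a, b in zip(shares, shares[1:]))

    def test_bad_parameter(self, toy_log):
        with pytest.raises(ParameterError):
            tn.superuser_set(toy_log, "top_percent_posts", 0)
        with pytest.raises(ParameterError):
            tn.superuser_set(toy_log, "top_elo", 1)


class TestWeeklyActiveSuperusers:
    def test_toy_week_zero(self, toy_log):
        su = tn.superuser_set(toy_log, "top_n_posts", 2)
        series = tn.weekly_active_superusers(toy_log, su)
        assert series["active_superusers"].iloc[0] == 2

    def test_bounded_by_cohort_size(self, blf_log):
        su = tn.superuser_set(blf_log, "top_percent_posts", 1.0)
        series = tn.weekly_active_superusers(blf_log, su)
        assert (series["active_superusers"] <= len(su)).all()

    def test_inactive_member_not_counted(self):
        ts = pd.Timestamp("2020-01-01T00:00:00+00:00")
        posts = [
            Post("p1", "t1", None, "A", ts, 1),
            Post("p2", "t2", None, "A", ts + pd.Timedelta(days=1), 1),
            Post("p3", "t3", None, "B", ts + pd.Timedelta(days=10), 1),
        ]
        log = PostLog(posts=posts)
        su = tn.superuser_set(log, "top_n_posts", 2)
        series = tn.weekly_active_superusers(log, su)
        assert series["active_superusers"].tolist() == [1, 1]


class TestInterpostingECDF:
    def test_hand_gaps(self):
        log = _log_one_user([0, 1, 3, 10])
        ecdf = tn.interposting_ecdf(log, users={"U"})
        assert ecdf.gaps.tolist() == [1, 2, 7]
        assert ecdf.fraction_below(2.0) == pytest.approx(2 / 3)

    def test_single_pair_jump(self):
        ecdf = tn.interposting_ecdf(_log_one_user([0, 5]), users={"U"})
        assert ecdf.fraction_below(4.999) == 0.0
        assert ecdf.fraction_below(5.0) == 1.0
        assert ecdf.quantile(1.0) == pytest.approx(5.0)

    def test_pooling_two_users(self):
        ts = pd.Timestamp("2020-01-01T00:00:00+00:00")
        posts = [
            Post("a1", "t1", None, "A", ts, 1),
            Post("a2", "t2", None, "A", ts + pd.Timedelta(days=1), 1),
            Post("b1", "t3", None, "B", ts, 1),
            Post("b2", "t4", None, "B", ts + pd.Timedelta(days=3), 1),
        ]
        ecdf = tn.interposting_ecdf(PostLog(posts=posts), users={"A", "B"})
        assert ecdf.fraction_below(2.0) == pytest.approx(0.5)

    def test_order_invariance(self):
        """Pooled ECDF does not depend on per-user processing order."""
        ts = pd.Timestamp("2020-01-01T00:00:00+00:00")
        rng = np.random.default_rng(0)
        posts = []
        for u in ("zeta", "alpha", "mid"):
            days = np.cumsum(rng.exponential(2.0, size=6))
            posts += [Post(f"{u}{i}", f"{u}t{i}", None, u,
                           ts + pd.Timedelta(days=float(d)), 1)
                      for i, d in enumerate(days)]
        log = PostLog(posts=posts)
        a = tn.interposting_ecdf(log, users={"zeta", "alpha", "mid"})
        b = tn.interposting_ecdf(log, users={"mid", "zeta", "alpha"})
        assert np.allclose(a.gaps, b.gaps)

    def test_no_eligible_user_raises(self, toy_log):
        with pytest.raises(EmptyInputError):
            tn.interposting_ecdf(toy_log, users={"B"})  # one post only


class TestPeriodogram:
    def test_pure_harmonic(self):
        t = np.arange(140)
        series = _series(10 + 5 * np.cos(2 * np.pi * t / 7))
        spec = tn.periodogram(series)
        assert spec.dominant_period == pytest.approx(7.0)

    def test_constant_series_flat(self):
        spec = tn.periodogram(_series(np.full(50, 3.0)))
        assert spec.power.max() == pytest.approx(0.0)
        assert spec.peaks == []

    def test_two_harmonics(self):
        t = np.arange(360)
        x = 20 + 6 * np.cos(2 * np.pi * t / 3) + 6 * np.cos(2 * np.pi * t / 30)
        spec = tn.periodogram(_series(x))
        top_periods = sorted(p for p, _ in spec.peaks[:2])
        assert top_periods == pytest.approx([3.0, 30.0])

    def test_too_short(self):
        with pytest.raises(ParameterError):
            tn.periodogram(_series(np.ones(5)))

    def test_boundary_bin_can_peak(self):
        t = np.arange(64)
        spec = tn.periodogram(_series(8 + 4 * np.cos(np.pi * t)))  # Nyquist
        assert spec.dominant_period == pytest.approx(2.0)

    @pytest.mark.parametrize("period", [2.0, 7.0, 30.0])
    def test_recovery_from_generator(self, period):
        """An injected intensity period with >= 10 cycles is recovered
        within one frequency bin."""
        duration = max(10 * period, 120.0)
        cfg = tn.SyntheticConfig(
            n_users=60, duration=duration, base_rate=30.0, lurker_fraction=0.3,
            periodic_components=[(period, 0.5)], seed=11)
        spec = tn.periodogram(tn.daily_counts(tn.generate_forum(cfg)))
        n = duration
        assert abs(1.0 / spec.dominant_period - 1.0 / period) <= 1.0 / n + 1e-12
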