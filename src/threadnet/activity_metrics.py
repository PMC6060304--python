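"""Posting-volume series, superusers, interposting times, periodicity.

Time is binned at daily resolution (floor of fractional days since the
first post) and aggregated to 7-day weeks anchored at the first post.
The periodicity analysis takes a discrete Fourier transform of the
mean-removed community-wide daily post counts; the power spectrum's
local maxima, converted from cycles/day to periods in days, are the
community's posting rhythms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParameterError
from .model import PostLog


# ----------------------------------------------------------------------
# volume series

@dataclass
class ActivitySeries:
    """Daily and weekly posting-volume series for one community."""

    days: np.ndarray                  # integer day index since origin
    daily_counts: np.ndarray
    weeks: np.ndarray
    weekly_counts: np.ndarray
    weekly_new_users: np.ndarray
    posts_per_user_per_week: np.ndarray

    @property
    def total_posts(self) -> int:
        return int(self.daily_counts.sum())


def daily_counts(log: PostLog) -> ActivitySeries:
    """Bin posts into integer days and derive weekly aggregates.

    ``posts_per_user_per_week`` divides each week's posts by the number
    of users who have posted by the end of that week (not by lifetime
    totals), matching the way weekly engagement is usually reported.
    """
    if not log.posts:
        raise EmptyInputError("daily_counts needs a non-empty log")
    t = log.times_days()
    day = np.floor(t).astype(int)
    n_days = int(day.max()) + 1
    daily = np.bincount(day, minlength=n_days)

    n_weeks = math.ceil(n_days / 7)
    padded = np.zeros(n_weeks * 7, dtype=int)
    padded[:n_days] = daily
    weekly = padded.reshape(n_weeks, 7).sum(axis=1)

    df = log.to_frame()
    first_post_week = np.floor(
        df.groupby("author_id")["t_days"].min().values / 7.0
    ).astype(int)
    new_users = np.bincount(first_post_week, minlength=n_weeks)
    cum_users = np.cumsum(new_users)
    with np.errstate(divide="ignore", invalid="ignore"):
        ppuw = np.where(cum_users > 0, weekly / cum_users, 0.0)

    return ActivitySeries(
        days=np.arange(n_days),
        daily_counts=daily,
        weeks=np.arange(n_weeks),
        weekly_counts=weekly,
        weekly_new_users=new_users,
        posts_per_user_per_week=ppuw,
    )


# ----------------------------------------------------------------------
# superusers

@dataclass
class SuperuserSet:
    """The community's most active users under a chosen selection mode."""

    mode: str
    parameter: float
    members: list[str]                # sorted by post count desc, id asc
    post_counts: dict[str, int]
    share_of_posts: float

    def __contains__(self, user_id: str) -> bool:
        return user_id in self.post_counts

    def __len__(self) -> int:
        return len(self.members)


def superuser_set(log: PostLog, mode: str = "top_percent_posts",
                  parameter: float = 1.0) -> SuperuserSet:
    """Select superusers by posting volume (or degree).

    Modes: ``top_percent_posts`` keeps the ceil(p% of posting users) top
    posters; ``top_n_posts`` keeps the top N posters; ``top_percent_degree``
    ranks by undirected reply-network degree instead. Ties broken by
    ascending user id.
    """
    if parameter <= 0:
        raise ParameterError("superuser selection parameter must be positive")
    counts = log.to_frame().groupby("author_id").size().to_dict()
    if mode in ("top_percent_posts", "top_n_posts"):
        score = counts
    elif mode == "top_percent_degree":
        from .network_build import build_reply_network, undirected_projection

        view = undirected_projection(build_reply_network(log))
        score = {u: view.graph.degree(u) if u in view.graph else 0 for u in counts}
    else:
        raise ParameterError(f"unknown superuser selection mode {mode!r}")

    ranked = sorted(score, key=lambda u: (-score[u], u))
    if mode == "top_n_posts":
        n = int(parameter)
    else:
        n = math.ceil(parameter / 100.0 * len(ranked))
    members = ranked[:n]
    total = sum(counts.values())
    member_posts = {u: int(counts[u]) for u in members}
    return SuperuserSet(
        mode=mode,
        parameter=parameter,
        members=sorted(members, key=lambda u: (-counts[u], u)),
        post_counts=member_posts,
        share_of_posts=(sum(member_posts.values()) / total) if total else 0.0,
    )


def weekly_active_superusers(log: PostLog, su: SuperuserSet) -> pd.DataFrame:
    """Unique superusers posting within each 7-day week."""
    df = log.to_frame()
    week = np.floor(df["t_days"].values / 7.0).astype(int)
    is_member = df["author_id"].isin(su.post_counts).values
    n_weeks = int(week.max()) + 1 if len(df) else 0
    rows = []
    for k in range(n_weeks):
        active = set(df.loc[(week == k) & is_member, "author_id"])
        rows.append({"week": k, "active_superusers": len(active)})
    return pd.DataFrame(rows, columns=["week", "active_superusers"])


# ----------------------------------------------------------------------
# interposting times

@dataclass
class ECDFTable:
    """Empirical CDF of pooled per-user interposting gaps (days)."""

    gaps: np.ndarray                  # sorted
    cum_fraction: np.ndarray
    n_users: int

    def fraction_below(self, x_days: float) -> float:
        """Fraction of gaps <= x_days."""
        return float(np.searchsorted(self.gaps, x_days, side="right") / len(self.gaps))

    def quantile(self, q: float) -> float:
        """Smallest gap g with ECDF(g) >= q."""
        if not 0.0 < q <= 1.0:
            raise ParameterError("quantile level must lie in (0, 1]")
        i = int(np.ceil(q * len(self.gaps))) - 1
        return float(self.gaps[max(i, 0)])


def interposting_ecdf(log: PostLog, users: set | None = None) -> ECDFTable:
    """Pool consecutive-post gaps per user and build their ECDF.

    ``users`` restricts the pool (default: the top 5% of users by post
    contribution); users with fewer than two posts are skipped.
    """
    if users is None:
        users = set(superuser_set(log, "top_percent_posts", 5.0).members)
    df = log.to_frame()
    df = df[df["author_id"].isin(users)]
    gaps = []
    for _, t in df.groupby("author_id")["t_days"]:
        if len(t) >= 2:
            gaps.append(np.diff(np.sort(t.values)))
    if not gaps:
        raise EmptyInputError("no user in the selection has two or more posts")
    pooled = np.sort(np.concatenate(gaps))
    frac = np.arange(1, len(pooled) + 1) / len(pooled)
    return ECDFTable(gaps=pooled, cum_fraction=frac, n_users=len(gaps))


# ----------------------------------------------------------------------
# periodicity

@dataclass
class Spectrum:
    """One-sided power spectrum of the daily posting series."""

    frequency: np.ndarray             # cycles/day, excludes the DC bin
    period: np.ndarray                # days, = 1/frequency
    power: np.ndarray
    peaks: list[tuple[float, float]]  # (period_days, power), power desc

    @property
    def dominant_period(self) -> float:
        if not self.peaks:
            raise EmptyInputError("spectrum has no peaks")
        return self.peaks[0][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency": self.frequency, "period_days": self.period,
                             "power": self.power})


def periodogram(series: ActivitySeries) -> Spectrum:
    """DFT power spectrum of the mean-removed daily counts.

    Power is the squared modulus of the discrete Fourier transform; no
    window function is applied. Peaks are local maxima of power over the
    frequency grid (boundary bins count when they exceed their single
    neighbour), sorted by power; nothing beyond the Nyquist frequency
    (2 samples/cycle) is ever reported.
    """
    x = series.daily_counts.astype(float)
    if len(x) < 8:
        raise ParameterError("periodogram needs a series of at least 8 days")
    x = x - x.mean()
    f = np.fft.rfftfreq(len(x), d=1.0)[1:]
    p = np.abs(np.fft.rfft(x))[1:] ** 2
    peaks = _local_maxima(f, p)
    return Spectrum(frequency=f, period=1.0 / f, power=p, peaks=peaks)


def _local_maxima(freq: np.ndarray, power: np.ndarray) -> list[tuple[float, float]]:
    if len(power) == 0 or power.max() == 0:
        return []
    idx = []
    for i in range(len(power)):
        left = power[i - 1] if i > 0 else -np.inf
        right = power[i + 1] if i < len(power) - 1 else -np.inf
        if power[i] > left and power[i] > right:
            idx.append(i)
    idx.sort(key=lambda i: -power[i])
    return [(float(1.0 / freq[i]), float(power[i])) for i in idx]
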