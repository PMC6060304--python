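"""Shared fixtures: a hand-built toy log and session-scoped synthetic logs."""

from __future__ import annotations

import pandas as pd
import pytest

import threadnet as tn
from threadnet.model import Post, PostLog, UserRecord


def _ts(day: float) -> pd.Timestamp:
    return pd.Timestamp("2020-01-01T00:00:00+00:00") + pd.Timedelta(days=day)


def make_toy_posts() -> list[Post]:
    """Five posts, three authors, two threads.

    t1: p1 root by A (day 0) <- p2 by B (day 1) <- p3 by A (day 2);
        p5 by C (day 4) also replies to p1.
    t2: p4 root by C (day 3).
    """
    return [
        Post("p1", "t1", None, "A", _ts(0), 1),
        Post("p2", "t1", "p1", "B", _ts(1), 2),
        Post("p3", "t1", "p2", "A", _ts(2), 3),
        Post("p4", "t2", None, "C", _ts(3), 1),
        Post("p5", "t1", "p1", "C", _ts(4), 2),
    ]


@pytest.fixture()
def toy_log() -> PostLog:
    return PostLog(posts=make_toy_posts())


@pytest.fixture()
def toy_log_with_lurkers() -> PostLog:
    users = {u: UserRecord(u) for u in "ABC"}
    users["D"] = UserRecord("D", join_date=_ts(0))
    users["E"] = UserRecord("E", join_date=_ts(1))
    return PostLog(posts=make_toy_posts(), users=users)


@pytest.fixture(scope="session")
def blf_log() -> PostLog:
    """Default daily-rhythm community preset, fixed seed, ~11k posts."""
    return tn.generate_forum(tn.preset_config("blf_like", seed=42))


@pytest.fixture(scope="session")
def blf_view(blf_log):
    return tn.undirected_projection(tn.build_reply_network(blf_log))
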