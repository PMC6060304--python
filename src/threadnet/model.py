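"""Core data model: posts, users, and the validated post log.

A *post log* is the single input of every analysis in this package: one
record per public forum post, carrying the post's position in its thread
(thread id, parent post, hierarchy level), its author, and an absolute
UTC timestamp. The accompanying user registry may be larger than the set
of authors — registered users who never wrote a post ("lurkers") are
first-class citizens of the registry and of the community-size
denominators downstream.

Internally all analyses measure time in fractional *days since the
earliest post* (the log's origin); durations and bins are therefore in
days and 7-day weeks throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("user", "moderator", "administrator")

#: seconds per day, used for every timestamp -> fractional-day conversion
_DAY = 86_400.0


@dataclass(frozen=True)
class Post:
    """One forum message.

    ``parent_post_id`` is ``None`` exactly for root posts (level 1); a
    reply to a level-*t* post sits at level *t + 1* in the same thread
    and cannot precede its parent in time.
    """

    post_id: str
    thread_id: str
    parent_post_id: str | None
    author_id: str
    timestamp: pd.Timestamp
    level: int
    author_role: str = "user"

    @property
    def is_root(self) -> bool:
        return self.parent_post_id is None


@dataclass(frozen=True)
class UserRecord:
    """Registry entry for one registered user (possibly a lurker)."""

    user_id: str
    join_date: pd.Timestamp | None = None
    leave_date: pd.Timestamp | None = None
    role: str = "user"


@dataclass
class PostLog:
    """Ordered collection of posts plus the user registry.

    Posts are kept sorted by ``(timestamp, post_id)``; the tie-break on
    identical timestamps is a convention of this package (the order of
    simultaneous posts is otherwise unobservable), chosen so that every
    run of every analysis is deterministic.
    """

    posts: list[Post]
    users: dict[str, UserRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.posts = sorted(self.posts, key=lambda p: (p.timestamp, p.post_id))
        # auto-register authors missing from a partial registry
        for p in self.posts:
            if p.author_id not in self.users:
                self.users[p.author_id] = UserRecord(p.author_id, role=p.author_role)
        self._frame: pd.DataFrame | None = None

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.posts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PostLog):
            return NotImplemented
        return self.posts == other.posts and self.users == other.users

    @property
    def origin_time(self) -> pd.Timestamp | None:
        """Timestamp of the earliest post, or None for an empty log."""
        return self.posts[0].timestamp if self.posts else None

    @property
    def span_days(self) -> float:
        """Days between the first and last post (0 for <= 1 post)."""
        if len(self.posts) < 2:
            return 0.0
        delta = self.posts[-1].timestamp - self.posts[0].timestamp
        return delta.total_seconds() / _DAY

    def times_days(self) -> np.ndarray:
        """Post times as fractional days since the origin, log order."""
        if not self.posts:
            return np.empty(0)
        origin = self.origin_time
        return np.array(
            [(p.timestamp - origin).total_seconds() / _DAY for p in self.posts]
        )

    def to_frame(self) -> pd.DataFrame:
        """Posts as a DataFrame (cached); adds ``t_days``, ``parent_author``.

        Columns: post_id, thread_id, parent_post_id (None for roots),
        author_id, timestamp, level, author_role, t_days, parent_author.
        """
        if self._frame is None:
            by_id = {p.post_id: p for p in self.posts}
            rows = {
                "post_id": [p.post_id for p in self.posts],
                "thread_id": [p.thread_id for p in self.posts],
                "parent_post_id": [p.parent_post_id for p in self.posts],
                "author_id": [p.author_id for p in self.posts],
                "timestamp": [p.timestamp for p in self.posts],
                "level": [p.level for p in self.posts],
                "author_role": [p.author_role for p in self.posts],
            }
            df = pd.DataFrame(rows)
            df["t_days"] = self.times_days()
            df["parent_author"] = [
                by_id[p.parent_post_id].author_id if p.parent_post_id in by_id else None
                for p in self.posts
            ]
            self._frame = df
        return self._frame

    # ------------------------------------------------------------------
    def posting_users(self) -> set[str]:
        return {p.author_id for p in self.posts}

    def lurkers(self) -> set[str]:
        return set(self.users) - self.posting_users()

    def posts_per_user(self) -> pd.Series:
        """Post counts for posting users, descending, ties by user_id."""
        s = self.to_frame().groupby("author_id").size()
        return s.sort_index().sort_values(ascending=False, kind="stable")


@dataclass(frozen=True)
class ValidationIssue:
    post_id: str | None
    rule: str
    message: str


@dataclass
class ValidationReport:
    """Outcome of :func:`threadnet.forum_io.validate_post_log`.

    ``errors`` is empty iff the log satisfies every structural invariant;
    ``counts`` mirrors the descriptive rows of a community summary table
    (posts with/without reply, posting users, lurkers).
    """

    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)
    counts: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors
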