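"""Community-level descriptive summary (the dataset-description table)."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import math

import numpy as np

from .activity_metrics import superuser_set
from .model import PostLog
from .network_build import build_reply_network, undirected_projection


@dataclass
class SummaryReport:
    """Descriptive statistics of one community, mirroring the standard
    dataset-description table: volume, reply coverage, user-base split
    (posting users, one-post users, lurkers), concentration of posting in
    the top contributors, and connectivity per user."""

    span_days: float
    span_weeks: int
    n_posts: int
    n_posts_with_reply: int
    n_posts_no_reply: int
    n_users: int
    n_posting_users: int
    n_one_post_users: int
    n_multi_post_users: int
    n_lurkers: int
    lurker_fraction: float
    posts_per_user_mean: float
    posts_per_user_sd: float
    posts_per_user_median: float
    posts_per_user_min: int
    posts_per_user_max: int
    top1pct_post_share: float
    top5pct_post_share: float
    connections_per_user_mean: float
    connections_per_user_median: float
    connections_per_superuser_mean: float
    connections_per_superuser_median: float

    def to_dict(self) -> dict:
        return asdict(self)


def _zero_report() -> SummaryReport:
    return SummaryReport(*([0] * 22))  # type: ignore[arg-type]


def summarize(log: PostLog) -> SummaryReport:
    """Compute every summary row from the log; empty log gives all zeros.

    Degrees count distinct reply partners (undirected); posting users who
    made no tie have degree 0. Superusers are the top 1% by post count.
    """
    if not log.posts:
        return _zero_report()

    df = log.to_frame()
    replied = set(df.loc[df["parent_post_id"].notna(), "parent_post_id"])
    counts = df.groupby("author_id").size()
    posting = set(counts.index)
    n_users = len(log.users)
    n_lurkers = n_users - len(posting)

    view = undirected_projection(build_reply_network(log))
    degree = {u: (view.graph.degree(u) if u in view.graph else 0) for u in posting}
    deg_arr = np.array(sorted(degree.values()))

    su = superuser_set(log, "top_percent_posts", 1.0)
    su5 = superuser_set(log, "top_percent_posts", 5.0)
    su_deg = np.array(sorted(degree[u] for u in su.members))

    return SummaryReport(
        span_days=float(log.span_days),
        span_weeks=max(1, math.ceil(log.span_days / 7.0)),
        n_posts=len(log.posts),
        n_posts_with_reply=len(replied),
        n_posts_no_reply=len(log.posts) - len(replied),
        n_users=n_users,
        n_posting_users=len(posting),
        n_one_post_users=int((counts == 1).sum()),
        n_multi_post_users=int((counts > 1).sum()),
        n_lurkers=n_lurkers,
        lurker_fraction=n_lurkers / n_users if n_users else 0.0,
        posts_per_user_mean=float(counts.mean()),
        posts_per_user_sd=float(counts.std(ddof=0)),
        posts_per_user_median=float(counts.median()),
        posts_per_user_min=int(counts.min()),
        posts_per_user_max=int(counts.max()),
        top1pct_post_share=su.share_of_posts,
        top5pct_post_share=su5.share_of_posts,
        connections_per_user_mean=float(deg_arr.mean()),
        connections_per_user_median=float(np.median(deg_arr)),
        connections_per_superuser_mean=float(su_deg.mean()) if len(su_deg) else 0.0,
        connections_per_superuser_median=float(np.median(su_deg)) if len(su_deg) else 0.0,
    )
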