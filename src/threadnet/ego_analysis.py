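"""Ego networks of thread starters and closed-triad analysis.

The ego network of a user is built from the threads that user *rooted*:
alters are the other users who posted in those threads, and undirected
edges among {ego} + alters come from the reply relations within those
threads (self-replies excluded, as everywhere in the package). A closed
triad centered on ego is a triangle ego-x-y: two alters both tied to ego
and to each other. A thread starter who never returns to their thread
tends to grow a star (all replies point at ego, alters mutually
disconnected); one who replies back into the thread ties themselves to
repliers-of-repliers and closes triads, knitting alters together.

The cohort-level summary correlates, across the most active users, the
number of closed triads in each ego network with the ego's level-2+
contribution to their own threads.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .activity_metrics import SuperuserSet
from .errors import InsufficientDataError, ParameterError
from .model import PostLog


@dataclass
class EgoNetwork:
    """Ego, the alters from ego's threads, and the ties among them."""

    ego: str
    graph: nx.Graph                   # contains ego plus alters
    n_threads: int

    @property
    def alters(self) -> set[str]:
        return set(self.graph.nodes) - {self.ego}


@dataclass
class TriadSummary:
    """Per-ego triads/contribution table with a cohort correlation."""

    table: pd.DataFrame               # ego_id, n_threads, n_level2plus_posts, n_triangles
    r: float
    p_value: float
    n: int
    degenerate: bool
    skipped: list[str]


def ego_network(log: PostLog, ego: str) -> EgoNetwork:
    """Restrict the reply network to threads rooted by ``ego``.

    Raises :class:`ParameterError` when ego never rooted a thread.
    """
    df = log.to_frame()
    rooted = set(df.loc[(df["level"] == 1) & (df["author_id"] == ego), "thread_id"])
    if not rooted:
        raise ParameterError(f"user {ego!r} rooted no thread")
    sub = df[df["thread_id"].isin(rooted)]
    g = nx.Graph()
    g.add_node(ego)
    replies = sub[sub["parent_post_id"].notna()]
    for u, v in zip(replies["author_id"], replies["parent_author"]):
        if u != v:
            g.add_edge(u, v)
    return EgoNetwork(ego=ego, graph=g, n_threads=len(rooted))


def count_ego_triangles(net: EgoNetwork) -> int:
    """Triangles containing ego: alter pairs tied to each other and to ego."""
    g = net.graph
    neighbors = list(g.neighbors(net.ego))
    return sum(1 for x, y in combinations(neighbors, 2) if g.has_edge(x, y))


def triads_vs_contribution(log: PostLog, cohort: SuperuserSet | list[str]) -> TriadSummary:
    """Correlate ego-triangle counts with egos' level-2+ contribution.

    For each cohort member who rooted at least one thread (others are
    skipped), count the triangles of their ego network and their level-2+
    posts within threads they rooted; summarise with Pearson's r and a
    two-sided t-approximation p-value. Raises
    :class:`InsufficientDataError` below 3 usable members; a zero-variance
    cohort is flagged ``degenerate`` with r = NaN.
    """
    members = cohort.members if isinstance(cohort, SuperuserSet) else list(cohort)
    df = log.to_frame()
    rows, skipped = [], []
    for ego in members:
        try:
            net = ego_network(log, ego)
        except ParameterError:
            skipped.append(ego)
            continue
        rooted = set(df.loc[(df["level"] == 1) & (df["author_id"] == ego), "thread_id"])
        own = df[(df["thread_id"].isin(rooted)) & (df["author_id"] == ego) & (df["level"] >= 2)]
        rows.append(
            {"ego_id": ego, "n_threads": net.n_threads,
             "n_level2plus_posts": int(len(own)),
             "n_triangles": count_ego_triangles(net)}
        )
    if len(rows) < 3:
        raise InsufficientDataError(
            f"only {len(rows)} cohort member(s) rooted a thread; need >= 3"
        )
    table = pd.DataFrame(rows)
    x = table["n_triangles"].values.astype(float)
    y = table["n_level2plus_posts"].values.astype(float)
    degenerate = (np.ptp(x) == 0) or (np.ptp(y) == 0)
    if degenerate:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(x, y)
    return TriadSummary(table=table, r=float(r), p_value=float(p),
                        n=len(rows), degenerate=bool(degenerate), skipped=skipped)
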