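"""Reply-network construction from post logs.

A directed edge u -> v with weight w means "user u wrote w reply posts to
posts authored by user v". The reply targets the author of the *parent*
post (the post actually being answered), not the thread's root author;
the level metadata makes the parent unambiguous. Self-replies (a user
answering their own post) create no edge: a tie requires two users.

Degree-based analyses (components, rich club, removal) operate on the
undirected projection, where the degree of a user is the number of
distinct users they exchanged replies with; direction is kept only for
help-seeking/help-giving semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .model import PostLog


@dataclass
class ReplyNetwork:
    """Directed weighted user-user reply graph (wrapping a DiGraph).

    ``as_of`` is the inclusive time bound in days since the log origin
    used to build the network, or None for the full log.
    """

    graph: nx.DiGraph
    as_of: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class UndirectedView:
    """Simple undirected projection; weights are summed over directions."""

    graph: nx.Graph

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_reply_network(log: PostLog, until: float | None = None) -> ReplyNetwork:
    """Reply network over posts with time <= ``until`` days (all if None).

    Nodes are users who authored a counted reply to another user, or were
    targeted by one; users who only wrote root posts (or self-replies)
    within the bound do not appear — they are isolated and enter the
    component analysis through the registry instead. Node attributes:
    ``posts`` (posts authored within the bound) and ``role``.
    """
    df = log.to_frame()
    g = nx.DiGraph()
    if len(df):
        mask = slice(None) if until is None else (df["t_days"].values <= until)
        sub = df if until is None else df[mask]
        posts_by_user = sub.groupby("author_id").size()
        replies = sub[sub["parent_post_id"].notna()]
        for src, dst in zip(replies["author_id"], replies["parent_author"]):
            if src == dst:
                continue
            if g.has_edge(src, dst):
                g[src][dst]["weight"] += 1
            else:
                g.add_edge(src, dst, weight=1)
        roles = {u.user_id: u.role for u in log.users.values()}
        for n in g.nodes:
            g.nodes[n]["posts"] = int(posts_by_user.get(n, 0))
            g.nodes[n]["role"] = roles.get(n, "user")
    return ReplyNetwork(graph=g, as_of=until)


def undirected_projection(net: ReplyNetwork) -> UndirectedView:
    """Collapse directions: {u, v} present iff u->v or v->u, weights summed."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes(data=True))
    for u, v, d in net.graph.edges(data=True):
        if g.has_edge(u, v):
            g[u][v]["weight"] += d["weight"]
        else:
            g.add_edge(u, v, weight=d["weight"])
    return UndirectedView(graph=g)


def weekly_cumulative_networks(log: PostLog) -> list[tuple[int, ReplyNetwork]]:
    """Cumulative reply-network snapshots at the end of each 7-day week.

    Week k covers days [7k, 7(k+1)) from the first post; the snapshot at
    week k accumulates all posts up to the end of that week, so snapshots
    are nested and the final one equals the full network. Returns an
    empty list for an empty log.
    """
    if not log.posts:
        return []
    n_weeks = max(1, math.ceil(log.span_days / 7.0))
    return [(k, build_reply_network(log, until=7.0 * (k + 1))) for k in range(n_weeks)]
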