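"""Reading, writing and validating post logs; network export.

File schema (the source forums published no schema, so this package fixes
one): a posts table with columns ``post_id, thread_id, parent_post_id,
author_id, timestamp, level, author_role`` where ``parent_post_id`` is
empty/null for root posts, ``timestamp`` is ISO 8601 with an explicit UTC
offset, and ``level`` is optional on input (recomputed from the parent
chain, and cross-checked when present). The user registry travels in an
optional sidecar table ``user_id, join_date, leave_date, role`` so that
lurkers — registered users with zero posts — survive a round trip.

Both tables exist as CSV and as JSONL (one object per line, same keys,
``null`` for missing values).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Iterable

import networkx as nx
import pandas as pd

from .errors import ConsistencyError, DanglingReferenceError, ParameterError, SchemaError
from .model import ROLES, Post, PostLog, UserRecord, ValidationIssue, ValidationReport

POST_COLUMNS = [
    "post_id",
    "thread_id",
    "parent_post_id",
    "author_id",
    "timestamp",
    "level",
    "author_role",
]
REQUIRED_POST_COLUMNS = ["post_id", "thread_id", "parent_post_id", "author_id", "timestamp"]
USER_COLUMNS = ["user_id", "join_date", "leave_date", "role"]


# ----------------------------------------------------------------------
# helpers

def _parse_ts(value) -> pd.Timestamp | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    ts = pd.Timestamp(value)
    if ts.tzinfo is None:
        raise SchemaError(f"timestamp {value!r} lacks a UTC offset")
    return ts.tz_convert("UTC")


def _fmt_ts(ts: pd.Timestamp | None) -> str:
    return "" if ts is None else ts.isoformat()


def _records_from_frame(df: pd.DataFrame) -> list[dict]:
    return df.to_dict("records")


def _load_table(source, fmt: str) -> list[dict]:
    if fmt == "csv":
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
        return _records_from_frame(df)
    if fmt == "jsonl":
        if hasattr(source, "read"):
            text = source.read()
            if isinstance(text, bytes):
                text = text.decode()
        else:
            text = Path(source).read_text()
        return [json.loads(line) for line in text.splitlines() if line.strip()]
    raise ParameterError(f"unknown format {fmt!r} (expected 'csv' or 'jsonl')")


def _none_if_blank(value):
    if value is None or value == "":
        return None
    return value


# ----------------------------------------------------------------------
# read

def read_post_log(source, format: str = "csv", users_source=None) -> PostLog:
    """Read a post log (and optional user-registry sidecar) from disk.

    Parameters
    ----------
    source : path or open text stream
        Posts table in the declared format.
    format : {'csv', 'jsonl'}
    users_source : path or stream, optional
        Registry sidecar; authors absent from it are auto-registered with
        null join/leave dates (a warning is attached at validation time).

    Raises
    ------
    SchemaError
        Missing required column, unknown role, or naive timestamp.
    DanglingReferenceError
        A ``parent_post_id`` that matches no post in the file.
    ConsistencyError
        A stored ``level`` that disagrees with the parent chain, or a
        parent chain containing a cycle.
    """
    records = _load_table(source, format)
    if records:
        missing = [c for c in REQUIRED_POST_COLUMNS if c not in records[0]]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    posts: list[Post] = []
    stored_levels: dict[str, int | None] = {}
    for rec in records:
        role = _none_if_blank(rec.get("author_role")) or "user"
        if role not in ROLES:
            raise SchemaError(f"unknown author_role {role!r} for post {rec['post_id']!r}")
        lvl = _none_if_blank(rec.get("level"))
        stored_levels[str(rec["post_id"])] = None if lvl is None else int(lvl)
        posts.append(
            Post(
                post_id=str(rec["post_id"]),
                thread_id=str(rec["thread_id"]),
                parent_post_id=_none_if_blank(rec.get("parent_post_id")),
                author_id=str(rec["author_id"]),
                timestamp=_parse_ts(rec["timestamp"]),
                level=0,  # recomputed below
                author_role=role,
            )
        )

    levels = recompute_levels(posts)
    for pid, stored in stored_levels.items():
        if stored is not None and stored != levels[pid]:
            raise ConsistencyError(
                f"post {pid!r} declares level {stored} but its parent chain "
                f"implies level {levels[pid]}"
            )
    posts = [
        Post(p.post_id, p.thread_id, p.parent_post_id, p.author_id, p.timestamp,
             levels[p.post_id], p.author_role)
        for p in posts
    ]

    users: dict[str, UserRecord] = {}
    if users_source is not None:
        for rec in _load_table(users_source, format):
            if "user_id" not in rec:
                raise SchemaError("missing required column(s): user_id")
            users[str(rec["user_id"])] = UserRecord(
                user_id=str(rec["user_id"]),
                join_date=_parse_ts(rec.get("join_date")),
                leave_date=_parse_ts(rec.get("leave_date")),
                role=_none_if_blank(rec.get("role")) or "user",
            )
    return PostLog(posts=posts, users=users)


def recompute_levels(posts: Iterable[Post]) -> dict[str, int]:
    """Hierarchy level per post id: 1 for roots, parent level + 1 otherwise."""
    by_id = {p.post_id: p for p in posts}
    levels: dict[str, int] = {}

    def resolve(pid: str, trail: set[str]) -> int:
        if pid in levels:
            return levels[pid]
        if pid in trail:
            raise ConsistencyError(f"parent chain through post {pid!r} is cyclic")
        post = by_id[pid]
        if post.parent_post_id is None:
            levels[pid] = 1
        else:
            if post.parent_post_id not in by_id:
                raise DanglingReferenceError(
                    f"post {pid!r} references missing parent {post.parent_post_id!r}"
                )
            levels[pid] = resolve(post.parent_post_id, trail | {pid}) + 1
        return levels[pid]

    for p in by_id:
        resolve(p, set())
    return levels


# ----------------------------------------------------------------------
# validate

def validate_post_log(log: PostLog) -> ValidationReport:
    """Check every structural invariant of a post log; never raises.

    Rules checked per post: root iff level 1; level = parent level + 1;
    timestamp >= parent timestamp; parent in the same thread; parent
    exists and precedes the post in log order. Registry rule: leave date
    not before join date. The counts section reports ``n_posts``,
    ``n_users``, ``n_posting_users``, ``n_lurkers``, ``lurker_fraction``,
    ``n_posts_with_reply`` and ``n_posts_no_reply``.
    """
    report = ValidationReport()
    by_id: dict[str, Post] = {}
    order: dict[str, int] = {}
    for i, p in enumerate(log.posts):
        by_id[p.post_id] = p
        order[p.post_id] = i

    def err(pid, rule, msg):
        report.errors.append(ValidationIssue(pid, rule, msg))

    replied_to: set[str] = set()
    for p in log.posts:
        if (p.parent_post_id is None) != (p.level == 1):
            err(p.post_id, "root-level",
                f"level {p.level} inconsistent with parent {p.parent_post_id!r}")
        if p.parent_post_id is not None:
            parent = by_id.get(p.parent_post_id)
            if parent is None:
                err(p.post_id, "dangling-parent",
                    f"parent {p.parent_post_id!r} not in log")
                continue
            replied_to.add(parent.post_id)
            if p.level != parent.level + 1:
                err(p.post_id, "level-chain",
                    f"level {p.level} but parent level {parent.level}")
            if p.timestamp < parent.timestamp:
                err(p.post_id, "time-order", "post precedes its parent")
            if p.thread_id != parent.thread_id:
                err(p.post_id, "thread-match",
                    f"thread {p.thread_id!r} differs from parent's {parent.thread_id!r}")
            if order[p.post_id] < order[p.parent_post_id]:
                err(p.post_id, "log-order", "parent appears later in the log")
        if p.author_id not in log.users:
            err(p.post_id, "author-registered", f"author {p.author_id!r} not registered")

    for u in log.users.values():
        if u.join_date is not None and u.leave_date is not None and u.leave_date < u.join_date:
            err(None, "membership-dates", f"user {u.user_id!r} leaves before joining")
        if u.join_date is None and u.user_id in log.posting_users():
            report.warnings.append(
                ValidationIssue(None, "auto-registered",
                                f"author {u.user_id!r} has no registry dates")
            )

    posting = log.posting_users()
    n_users = len(log.users)
    n_lurk = n_users - len(posting)
    report.counts = {
        "n_posts": len(log.posts),
        "n_users": n_users,
        "n_posting_users": len(posting),
        "n_lurkers": n_lurk,
        "lurker_fraction": (n_lurk / n_users) if n_users else 0.0,
        "n_posts_with_reply": len(replied_to),
        "n_posts_no_reply": len(log.posts) - len(replied_to),
    }
    return report


# ----------------------------------------------------------------------
# write

def write_post_log(log: PostLog, sink, format: str = "csv", users_sink=None) -> None:
    """Write a post log so that reading it back reproduces the log exactly.

    ``users_sink`` (optional) receives the registry sidecar; without it,
    lurkers and join/leave dates are not representable in the output.
    """
    post_rows = [
        {
            "post_id": p.post_id,
            "thread_id": p.thread_id,
            "parent_post_id": p.parent_post_id if p.parent_post_id is not None else "",
            "author_id": p.author_id,
            "timestamp": _fmt_ts(p.timestamp),
            "level": p.level,
            "author_role": p.author_role,
        }
        for p in log.posts
    ]
    user_rows = [
        {
            "user_id": u.user_id,
            "join_date": _fmt_ts(u.join_date),
            "leave_date": _fmt_ts(u.leave_date),
            "role": u.role,
        }
        for u in sorted(log.users.values(), key=lambda u: u.user_id)
    ]
    _dump_table(post_rows, POST_COLUMNS, sink, format)
    if users_sink is not None:
        _dump_table(user_rows, USER_COLUMNS, users_sink, format)


def _dump_table(rows: list[dict], columns: list[str], sink, fmt: str) -> None:
    if fmt == "csv":
        df = pd.DataFrame(rows, columns=columns)
        df.to_csv(sink, index=False)
    elif fmt == "jsonl":
        text = "\n".join(json.dumps({k: (r[k] if r[k] != "" else None) for k in columns})
                         for r in rows)
        if rows:
            text += "\n"
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            Path(sink).write_text(text)
    else:
        raise ParameterError(f"unknown format {fmt!r} (expected 'csv' or 'jsonl')")


# ----------------------------------------------------------------------
# network export

def export_network(net, sink, format: str = "edge_csv") -> None:
    """Export a reply network for external viewers.

    ``edge_csv`` writes directed rows ``source,target,weight``; ``graphml``
    writes the full graph with node attributes (``posts``, ``degree``) and
    the edge ``weight`` (number of reply posts), readable by generic graph
    software.
    """
    g = net.graph
    if format == "edge_csv":
        rows = [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(sink, index=False)
    elif format == "graphml":
        out = g.copy()
        for n in out.nodes:
            out.nodes[n].setdefault("posts", 0)
            out.nodes[n]["degree"] = g.degree(n)
            # GraphML cannot serialise None-valued attributes
            for key in [k for k, v in out.nodes[n].items() if v is None]:
                del out.nodes[n][key]
        nx.write_graphml(out, sink)
    else:
        raise ParameterError(f"unknown export format {format!r}")
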