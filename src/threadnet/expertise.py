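"""Help-seeking vs help-giving classification and the expertise z-score.

Structurally, starting a thread (a level-1 post) is help-seeking and any
reply (level >= 2) is help-giving. For user i with a_i help-giving and
q_i help-seeking posts, n_i = a_i + q_i, and a community-wide answer
probability P_a, posting is modelled as a Bernoulli process: a random
user writing n_i posts would give a_random ~ Binomial(n_i, P_a) answers,
with mean n_i * P_a and standard deviation sqrt(n_i * P_a * (1 - P_a)).
The expertise z-score is the standardized excess of observed answers,

    z_i = (a_i - n_i P_a) / sqrt(n_i P_a (1 - P_a)),

positive for predominant help-givers, negative for help-seekers, and
zero when the user's mix matches the community's. With P_a = 2/3 the
expression reduces to the closed form z_i = (a_i - 2 q_i) / sqrt(2 n_i).

P_a is estimated from the input log (it is an empirical property of each
community, not a constant); callers may override it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, ParameterError
from .model import PostLog


@dataclass(frozen=True)
class HelpCounts:
    """Per-user help-seeking (q) and help-giving (a) post counts."""

    user_id: str
    q: int
    a: int

    @property
    def n(self) -> int:
        return self.a + self.q


@dataclass
class ZScoreTable:
    """Per-user counts and z-scores plus the global answer probability."""

    table: pd.DataFrame               # user_id, q, a, n, z
    p_a: float

    @property
    def p_q(self) -> float:
        return 1.0 - self.p_a


def classify_posts(log: PostLog) -> list[HelpCounts]:
    """Count level-1 (q) and level-2+ (a) posts per posting user."""
    df = log.to_frame()
    if df.empty:
        return []
    grouped = df.assign(is_reply=df["level"] >= 2).groupby("author_id")["is_reply"]
    out = []
    for user, s in grouped:
        a = int(s.sum())
        out.append(HelpCounts(user_id=user, q=int(len(s) - a), a=a))
    return sorted(out, key=lambda h: h.user_id)


def estimate_answer_probability(counts: list[HelpCounts]) -> float:
    """P_a = total help-giving posts / total posts."""
    total = sum(h.n for h in counts)
    if total < 1:
        raise EmptyInputError("cannot estimate P_a from zero posts")
    return sum(h.a for h in counts) / total


def z_score(counts: HelpCounts, p_a: float) -> float:
    """Standardized excess of help-giving posts under the Bernoulli model."""
    if counts.n < 1:
        raise EmptyInputError("z-score is undefined for a user with no posts")
    if not 0.0 < p_a < 1.0:
        raise ParameterError("the Bernoulli model degenerates at P_a in {0, 1}")
    n = counts.n
    return (counts.a - n * p_a) / np.sqrt(n * p_a * (1.0 - p_a))


def z_score_closed_form(a: int, q: int) -> float:
    """The P_a = 2/3 special case, z = (a - 2q) / sqrt(2 (a + q))."""
    if a + q < 1:
        raise EmptyInputError("z-score is undefined for a user with no posts")
    return (a - 2.0 * q) / np.sqrt(2.0 * (a + q))


def z_score_table(log: PostLog, p_a: float | None = None) -> ZScoreTable:
    """Full per-user z-score table; P_a estimated from the log by default."""
    counts = classify_posts(log)
    if not counts:
        raise EmptyInputError("no posting users")
    if p_a is None:
        p_a = estimate_answer_probability(counts)
    rows = [
        {"user_id": h.user_id, "q": h.q, "a": h.a, "n": h.n, "z": z_score(h, p_a)}
        for h in counts
    ]
    return ZScoreTable(table=pd.DataFrame(rows), p_a=p_a)


def z_vs_activity(table: ZScoreTable) -> dict:
    """Pair each user's total posts n with their z, plus a rank-correlation
    summary (Spearman) of the activity-expertise trend.

    Returns a dict with ``pairs`` (DataFrame of n, z), ``rho``, ``p_value``
    and ``degenerate`` (True when either variable has zero variance, in
    which case rho is NaN).
    """
    df = table.table
    if len(df) < 2:
        raise EmptyInputError("z_vs_activity needs at least 2 users")
    n = df["n"].values.astype(float)
    z = df["z"].values
    degenerate = (np.ptp(n) == 0) or (np.ptp(z) == 0)
    if degenerate:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(n, z)
    return {
        "pairs": df[["user_id", "n", "z"]].copy(),
        "rho": float(rho),
        "p_value": float(p),
        "degenerate": bool(degenerate),
    }
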