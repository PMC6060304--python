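"""Seeded generator of synthetic threaded-forum post logs.

The private community datasets behind this kind of analysis are never
deposited, so the pipeline is exercised on synthetic logs that reproduce
the *statistical* structure the analyses assume:

* a lurker majority — a configurable, exact fraction of registered users
  never writes a post;
* heavy-tailed posting propensity — a small core of very active users
  writes most posts (truncated discrete power law, or lognormal);
* a roughly 2:1 answer:question mix — each posting event is a reply with
  probability ``answer_probability`` and a new thread otherwise;
* recency-driven threading — replies target recent posts, with an
  exponential kernel of configurable half-life;
* anti-rich-club mixing — reply targets are biased *away* from posts by
  already-active authors, so highly connected users end up talking to
  poorly connected ones;
* root-poster follow-ups — thread starters reply back to replies in
  their threads, which closes triads in their ego networks;
* periodic daily intensity — the event rate is modulated by cosine
  components (e.g. a 2-day cycle) recoverable by the periodogram.

Every draw flows from a single integer seed: the same config and seed
give a byte-identical log.

Design note: follow-up replies are extra posts scheduled shortly after
the reply that triggers them. Because they are all level-2+ they would
inflate the answer share, so the per-event reply probability of the base
stream is set to p = P_a / (1 + f (1 - P_a)), which makes the *overall*
share of level-2+ posts (base replies plus follow-ups) equal to the
configured ``answer_probability`` in expectation — the answer:question
mix is a calibration target and must survive the follow-up mechanism.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError
from .model import Post, PostLog, UserRecord

_ORIGIN = pd.Timestamp("2015-01-01T00:00:00+00:00")
_LN2 = float(np.log(2.0))

#: replies only consider this many most-recent candidate posts; with the
#: default 2-day half-life, older posts carry negligible weight anyway
_CANDIDATE_WINDOW = 1500

#: mean delay, in days, between a reply and the root poster's follow-up
_FOLLOWUP_MEAN_DELAY = 0.25

#: the anti-rich-club target bias applies to repliers who already wrote
#: more than this many posts (the community's active core); casual
#: repliers pick targets by recency alone. Biasing everyone would make
#: low-activity users seek each other out too, which *raises* the mid-k
#: rich-club ratio instead of producing the intended hub-to-periphery
#: mixing.
_CORE_ACTIVITY = 5


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic community.

    Attributes
    ----------
    n_users : int
        Registered users (posters + lurkers).
    duration : float
        Observation span in days.
    base_rate : float
        Mean posting events per day before periodic modulation.
    lurker_fraction : float
        Exact fraction of users who never post (rounded to a count).
    activity_dist : {'powerlaw', 'lognormal'}
        Shape of the per-user posting propensity.
    activity_alpha : float
        Power-law exponent (propensity pmf ~ x**-alpha, truncated at the
        realized event count).
    activity_sigma : float
        Lognormal sigma, used when ``activity_dist == 'lognormal'``.
    answer_probability : float
        Probability that a posting event is a reply (level >= 2).
    recency_half_life : float
        Half-life, in days, of the reply-target recency kernel.
    anti_richclub_strength : float
        Exponent s >= 0 biasing reply targets toward posts by
        low-activity authors: weight ~ (1 + author activity)**-s. The
        bias applies to repliers already in the active core (more than
        5 posts written so far); casual repliers follow recency alone,
        so the mixing is hub-to-periphery rather than low-to-low.
    followup_probability : float
        Probability that a reply in a thread triggers a later reply back
        from the thread's root poster (closing a triad).
    periodic_components : list of (period_days, depth)
        Cosine modulation of the daily intensity,
        rate(t) = base_rate * (1 + sum depth_j * cos(2 pi t / T_j)).
    seed : int
        Master seed for all randomness in the generator.
    """

    n_users: int
    duration: float
    base_rate: float
    lurker_fraction: float = 0.6
    activity_dist: str = "powerlaw"
    activity_alpha: float = 2.0
    activity_sigma: float = 1.0
    answer_probability: float = 2.0 / 3.0
    recency_half_life: float = 2.0
    anti_richclub_strength: float = 0.0
    followup_probability: float = 0.3
    periodic_components: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 1:
            raise ConfigError("n_users must be >= 1")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.base_rate * self.duration < 1:
            raise ConfigError("infeasible config: base_rate * duration < 1")
        for name in ("lurker_fraction", "answer_probability", "followup_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.anti_richclub_strength < 0:
            raise ConfigError("anti_richclub_strength must be >= 0")
        if self.recency_half_life <= 0:
            raise ConfigError("recency_half_life must be positive")
        if self.activity_dist not in ("powerlaw", "lognormal"):
            raise ConfigError(f"unknown activity_dist {self.activity_dist!r}")
        for period, depth in self.periodic_components:
            if period <= 0:
                raise ConfigError("periodic component periods must be positive")
            if not 0.0 <= depth <= 1.0:
                raise ConfigError("modulation depths must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["periodic_components"] = [list(pc) for pc in self.periodic_components]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["periodic_components"] = [tuple(pc) for pc in d.get("periodic_components", [])]
        return cls(**d)


_PRESETS = {
    # daily-rhythm community: large, busy, strong 2-day posting cycle
    "blf_like": dict(
        n_users=5000,
        duration=460.0,
        base_rate=25.0,
        lurker_fraction=0.6,
        answer_probability=2.0 / 3.0,
        recency_half_life=2.0,
        anti_richclub_strength=2.0,
        followup_probability=0.3,
        periodic_components=[(2.0, 0.5)],
    ),
    # episodic community: smaller, slower, weekly plus ~6-monthly cycles
    "asthma_like": dict(
        n_users=1500,
        duration=1092.0,
        base_rate=6.0,
        lurker_fraction=0.65,
        answer_probability=2.0 / 3.0,
        recency_half_life=3.0,
        anti_richclub_strength=2.0,
        followup_probability=0.3,
        periodic_components=[(7.0, 0.4), (182.0, 0.4)],
    ),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Documented defaults for the two bundled community presets.

    ``blf_like`` carries a 2-day periodic component; ``asthma_like`` a
    7-day and a ~182-day one. Keyword overrides replace preset fields.
    """
    if name not in _PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_PRESETS))}"
        )
    params = dict(_PRESETS[name])
    params.update(overrides)
    return SyntheticConfig(seed=seed, **params)


# ----------------------------------------------------------------------

def _propensities(config: SyntheticConfig, n: int, cap: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-user posting propensity weights (heavy-tailed)."""
    if config.activity_dist == "lognormal":
        return rng.lognormal(0.0, config.activity_sigma, n)
    # truncated discrete power law on 1..cap via inverse CDF
    support = np.arange(1, max(cap, 2) + 1, dtype=float)
    pmf = support ** (-config.activity_alpha)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    return support[np.searchsorted(cdf, rng.random(n))]


def _event_times(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Event times (fractional days) from the modulated daily intensity."""
    n_days = int(np.ceil(config.duration))
    day = np.arange(n_days, dtype=float)
    rate = np.full(n_days, config.base_rate)
    for period, depth in config.periodic_components:
        rate = rate + config.base_rate * depth * np.cos(2.0 * np.pi * day / period)
    rate = np.clip(rate, 0.0, None)
    counts = rng.poisson(rate)
    times = np.repeat(day, counts) + rng.random(int(counts.sum()))
    times = times[times < config.duration]
    times.sort()
    return times


def generate_forum(config: SyntheticConfig) -> PostLog:
    """Generate a synthetic post log. Deterministic given ``config.seed``.

    Exactly ``round(n_users * lurker_fraction)`` users never post; every
    other user posts at least once (their first post is planted at a
    random event slot). Raises :class:`ConfigError` when the realized
    event stream is too small to give every active user a post.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    times = _event_times(config, rng)
    n_events = len(times)
    if n_events == 0:
        raise ConfigError("infeasible config: no posting events realized")

    n_lurkers = int(round(config.n_users * config.lurker_fraction))
    n_active = config.n_users - n_lurkers
    if n_active < 1:
        raise ConfigError("infeasible config: no active users")
    if n_events < n_active:
        raise ConfigError(
            f"infeasible config: {n_events} events cannot cover {n_active} active users"
        )

    width = max(4, len(str(config.n_users)))
    user_ids = [f"u{i:0{width}d}" for i in range(config.n_users)]
    perm = rng.permutation(config.n_users)
    active = perm[:n_active]          # global user indices that will post
    lurker_idx = perm[n_active:]

    weights = _propensities(config, n_active, n_events, rng)
    cum_w = np.cumsum(weights)
    total_w = cum_w[-1]

    # plant each active user's first post at a distinct random event slot
    debut_slots = rng.choice(n_events, size=n_active, replace=False)
    debut_at = dict(zip(debut_slots.tolist(), rng.permutation(n_active).tolist()))

    # follow-ups are extra level-2+ posts, so the base stream replies less
    # often than the configured overall answer share (see module docstring)
    f = config.followup_probability
    p_a = config.answer_probability
    p_reply = p_a / (1.0 + f * (1.0 - p_a))
    is_reply = rng.random(n_events) < p_reply

    # per-post state (posts = stream events + scheduled follow-ups)
    cap = 2 * n_events
    post_time = np.empty(cap)
    post_author = np.empty(cap, dtype=np.int64)          # index into `active`
    post_level = np.empty(cap, dtype=np.int64)
    post_parent = np.full(cap, -1, dtype=np.int64)
    post_thread = np.empty(cap, dtype=np.int64)
    activity = np.zeros(n_active)                        # posts so far per active user
    thread_root: list[int] = []                          # root author per thread
    pending: list[tuple[float, int, int]] = []           # heap: (time, tiebreak, target)
    s = config.anti_richclub_strength
    hl = config.recency_half_life
    n_posts = 0
    n_sched = 0

    def emit_followup(t: float, target: int) -> None:
        nonlocal n_posts
        tid = post_thread[target]
        author = thread_root[tid]
        post_time[n_posts] = t
        post_author[n_posts] = author
        post_level[n_posts] = post_level[target] + 1
        post_parent[n_posts] = target
        post_thread[n_posts] = tid
        activity[author] += 1.0
        n_posts += 1

    for k in range(n_events):
        t = times[k]
        while pending and pending[0][0] <= t:
            ft, _, tgt = heapq.heappop(pending)
            emit_followup(ft, tgt)

        debut = debut_at.get(k)
        author = debut
        target = -1
        if is_reply[k] and n_posts > 0:
            if author is None:
                author = int(np.searchsorted(cum_w, rng.random() * total_w))
            lo = max(0, n_posts - _CANDIDATE_WINDOW)
            w = np.exp(-(t - post_time[lo:n_posts]) * _LN2 / hl)
            if s and activity[author] > _CORE_ACTIVITY:
                w = w * (1.0 + activity[post_author[lo:n_posts]]) ** (-s)
            cw = np.cumsum(w)
            target = lo + int(np.searchsorted(cw, rng.random() * cw[-1]))
        elif author is None:
            author = int(np.searchsorted(cum_w, rng.random() * total_w))

        post_time[n_posts] = t
        post_author[n_posts] = author
        if target >= 0:
            post_parent[n_posts] = target
            post_level[n_posts] = post_level[target] + 1
            tid = post_thread[target]
            post_thread[n_posts] = tid
            if author != thread_root[tid] and rng.random() < f:
                ft = t + rng.exponential(_FOLLOWUP_MEAN_DELAY)
                if ft < config.duration:
                    heapq.heappush(pending, (ft, n_sched, n_posts))
                    n_sched += 1
        else:
            post_level[n_posts] = 1
            post_thread[n_posts] = len(thread_root)
            thread_root.append(author)
        activity[author] += 1.0
        n_posts += 1

    while pending:
        ft, _, tgt = heapq.heappop(pending)
        emit_followup(ft, tgt)
    n_events = n_posts

    # materialize posts and registry
    pw = max(6, len(str(n_events)))
    tw = max(5, len(str(len(thread_root))))
    posts: list[Post] = []
    first_post_ts: dict[int, pd.Timestamp] = {}
    for k in range(n_events):
        ts = _ORIGIN + pd.Timedelta(microseconds=int(round(post_time[k] * 86_400e6)))
        gidx = int(active[post_author[k]])
        posts.append(
            Post(
                post_id=f"p{k:0{pw}d}",
                thread_id=f"t{int(post_thread[k]):0{tw}d}",
                parent_post_id=None if post_parent[k] < 0 else f"p{int(post_parent[k]):0{pw}d}",
                author_id=user_ids[gidx],
                timestamp=ts,
                level=int(post_level[k]),
                author_role="user",
            )
        )
        first_post_ts.setdefault(gidx, ts)

    users: dict[str, UserRecord] = {}
    lurker_joins = rng.random(len(lurker_idx)) * config.duration
    for i, gidx in enumerate(lurker_idx):
        uid = user_ids[int(gidx)]
        join = _ORIGIN + pd.Timedelta(microseconds=int(round(lurker_joins[i] * 86_400e6)))
        users[uid] = UserRecord(uid, join_date=join)
    for gidx, ts in first_post_ts.items():
        uid = user_ids[gidx]
        users[uid] = UserRecord(uid, join_date=ts)

    return PostLog(posts=posts, users=users)


# ----------------------------------------------------------------------

def generate_followup_cohort(
    n_egos: int = 50,
    seed: int = 0,
    followup_max: float = 0.9,
    n_users: int = 15,
    duration: float = 40.0,
    base_rate: float = 8.0,
) -> tuple[PostLog, list[str]]:
    """Merge ``n_egos`` small communities whose follow-up propensity varies
    from 0 to ``followup_max``, and return the merged log plus one ego per
    community (its most prolific thread starter).

    Used to demonstrate that root-poster follow-ups drive triad closure:
    across the cohort, egos with higher follow-up probability contribute
    more level-2+ posts to their own threads and accumulate more closed
    triads. The member communities use a low-variance lognormal posting
    propensity so exposure (threads rooted, replies received) is
    comparable across egos and the follow-up effect is not drowned by
    heavy-tail variance in community size.
    """
    rng = np.random.default_rng(seed)
    all_posts: list[Post] = []
    all_users: dict[str, UserRecord] = {}
    egos: list[str] = []
    for i in range(n_egos):
        f = followup_max * i / max(n_egos - 1, 1)
        cfg = SyntheticConfig(
            n_users=n_users,
            duration=duration,
            base_rate=base_rate,
            lurker_fraction=0.0,
            activity_dist="lognormal",
            activity_sigma=0.3,
            answer_probability=2.0 / 3.0,
            recency_half_life=2.0,
            anti_richclub_strength=0.0,
            followup_probability=f,
            seed=int(rng.integers(2**31)),
        )
        sub = generate_forum(cfg)
        prefix = f"c{i:03d}_"
        posts = [
            Post(
                post_id=prefix + p.post_id,
                thread_id=prefix + p.thread_id,
                parent_post_id=None if p.parent_post_id is None else prefix + p.parent_post_id,
                author_id=prefix + p.author_id,
                timestamp=p.timestamp,
                level=p.level,
                author_role=p.author_role,
            )
            for p in sub.posts
        ]
        all_posts.extend(posts)
        for uid, u in sub.users.items():
            all_users[prefix + uid] = UserRecord(prefix + uid, u.join_date, u.leave_date, u.role)
        roots = {}
        for p in posts:
            if p.is_root:
                roots[p.author_id] = roots.get(p.author_id, 0) + 1
        egos.append(min(roots, key=lambda u: (-roots[u], u)))
    return PostLog(posts=all_posts, users=all_users), egos
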