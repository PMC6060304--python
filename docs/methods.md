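# Methods

This package analyses the structure and dynamics of threaded online
peer-support communities from their post logs alone: one record per
public post with author, timestamp, thread id, parent post and hierarchy
level. Everything downstream — networks, robustness, rhythms, expertise
— is derived from that single table plus an optional user registry that
also lists members who never posted (lurkers).

## Reply networks

A directed edge u → v with weight w means u wrote w replies to posts
authored by v. Two conventions matter and are fixed here:

* **Parent author, not root author.** A reply is an answer to the post
  it is attached to; the edge therefore targets the author of the
  *immediate parent* (the level metadata makes the parent unambiguous),
  not the author of the thread's root.
* **No self-loops.** A tie is a connection between two users;
  self-replies are kept as posts (they count as level-2+ contributions)
  but create no edge.

Degree-based analyses (components, removal, rich club) use the
undirected projection, in which a user's degree is the number of
distinct users they exchanged replies with, with edge weights summed
over the two directions. Direction is retained only where the
help-seeking/help-giving semantics needs it.

Temporal analyses measure time in fractional days since the first post
and aggregate into half-open 7-day weeks anchored there. Cumulative
weekly snapshots take all posts up to the end of each week; because
timestamps are continuous, counting the boundary instant itself
(a measure-zero event) is immaterial, and the final snapshot equals the
full network by construction. The largest-component fraction divides by
the number of users who have *posted* by that week: lurkers cannot be
connected, and including them would bound the fraction away from 1
regardless of network structure. Posting ties at identical timestamps
are ordered by post id — a determinism convention, since the true order
of simultaneous posts is unobservable.

## Robustness to superuser removal

Nodes are ranked once by descending degree on the intact network (ties
by ascending user id); for each removal fraction f the top ⌈f·N⌉ ranked
users are deleted and the surviving largest component is reported as a
fraction of the original largest component. The ranking is static, not
recomputed after each deletion: the question asked is "what happens if
the best-connected users disappear", not "what is the optimal attack".
The curve starts at 1 by definition and is nonincreasing.

## Rich club and its null

The raw rich-club coefficient at threshold k is the edge density among
S_k = {v : deg(v) ≥ k},

    R(k) = 2 E(S_k) / (|S_k|(|S_k|−1)),

undefined when |S_k| < 2 ("degree k or larger" — the threshold is ≥ k).
R(k) rises mechanically with k in any graph, so it is normalized by the
mean of R(k) over M independent degree-preserving randomizations of the
same graph: ρ(k) = R(k) / ⟨R_rand(k)⟩. ρ > 1 indicates a rich club;
ρ < 1 the anti-rich-club regime in which well-connected users
preferentially talk to poorly connected ones.

The null model is the standard double-edge-swap chain: each attempt
picks two edges (u,v), (x,y) and proposes (u,x), (v,y) (random
orientation), rejecting self-loops and duplicate edges. The degree
multiset is preserved exactly, so S_k is identical in graph and null and
ρ(k_min) ≡ 1 at the smallest observed degree. Defaults: M = 20 nulls and
10·|E| swap attempts — enough for the null standard error to be far
below the effects of interest at desk scale — both configurable. The
default threshold grid covers observed degrees up to the 90th
percentile; higher thresholds are mostly undefined. When the null mean
is zero the ratio is flagged undefined rather than reported.

## Posting rhythms, interposting times, superusers

The periodogram is the squared modulus of the DFT of the *mean-removed*
community-wide daily post counts. No window or detrending beyond mean
removal is applied: the series analysed are stationary by construction
in the synthetic communities, and the peaks of interest are far above
the noise floor. Peaks are local maxima of power on the frequency grid
(a boundary bin counts if it exceeds its single neighbour — the 2-day
rhythm sits exactly at Nyquist on a daily grid); periods are reported in
days as 1/frequency, and nothing beyond 2 samples/cycle is reported.
Day bins are floors of fractional days.

Interposting times are consecutive-post gaps per user, pooled across a
user set (default: top 5% of users by post count) into one empirical
CDF; users with fewer than two posts are skipped. Superusers default to
the top 1% of posting users by lifetime post count (ceil of the
percentage, ties by user id); the weekly-presence series counts distinct
cohort members posting in each week.

## Expertise z-score

Starting a thread (level 1) is help-seeking; replying (level ≥ 2) is
help-giving, including self-replies — the operationalization is
structural, not semantic. With per-user counts a (answers) and q
(questions), n = a + q, posting is modelled as a Bernoulli process with
community-wide answer probability P_a, and

    z = (a − n·P_a) / sqrt(n·P_a·(1 − P_a)),

the standardized excess of observed help-giving. P_a is *estimated from
the input log* (Σa / Σn) rather than fixed: it is an empirical property
of each community. At P_a = 2/3 the score reduces to the closed form
(a − 2q)/√(2n), which the tests verify against the generic expression to
machine precision. The activity–expertise trend is summarised with
Spearman's rank correlation (the relationship is monotone at best, not
linear).

## Ego networks and triads

The ego network of a user is induced by the threads that user rooted:
alters are other users posting there, edges are the reply relations
within those threads, projected undirected. Closed triads are triangles
*containing ego* (alter–alter–alter triangles are ignored: the question
is whether ego's behaviour knits their audience together). Each ego
contributes one point — triangles summed over all threads they rooted
against their level-2+ posts within those threads — and the cohort
summary is Pearson's r with a two-sided t-approximation p-value, over
the top 5% of contributors by default. Cohort members who rooted no
thread are skipped with a warning; fewer than three usable members is an
error; zero variance in either variable is flagged degenerate rather
than reported as a correlation.

## The synthetic community generator

No real community data ships with this package, so the generator
produces post logs with the statistical structure the analyses assume.
It is an event-stream model, not an agent simulation:

1. **Event times.** Daily intensity λ(t) = base_rate · (1 + Σ m_j
   cos(2πt/T_j)), sampled as Poisson counts per day with uniform
   within-day placement. Defaults: the `blf_like` preset (5,000 users,
   460 days, 25 events/day, one 2-day component of depth 0.5) emulates a
   large busy community with a strong short rhythm; `asthma_like`
   (1,500 users, 1,092 days, 6 events/day, 7-day and 182-day components
   of depth 0.4) a smaller episodic one with weekly and half-yearly
   rhythms.
2. **Who posts.** An exact count round(n_users · lurker_fraction) of
   users never posts (0.6 / 0.65 in the presets). Posting propensity is
   heavy-tailed — truncated discrete power law with exponent 2 by
   default (lognormal available) — which reproduces superuser
   concentration (top 1% holding ≫ 10% of posts) without extra
   parameters. Every active user's first post is planted at a distinct
   random event slot so the lurker count is exact, not binomial;
   configs whose event stream cannot cover the active users are
   rejected as infeasible.
3. **Root or reply.** Each stream event is a reply with probability
   p = P_a / (1 + f(1−P_a)) and a new thread otherwise, where P_a is the
   configured answer share (2/3 in both presets) and f the follow-up
   probability below. The compensation makes the *overall* level-2+
   share — base replies plus follow-ups — equal P_a in expectation, so
   estimating the answer probability from a generated log round-trips
   the configured value.
4. **Reply targets.** A reply picks an earlier post with weight
   exp(−Δt·ln2/half-life), restricted to the 1,500 most recent posts
   (older posts carry negligible weight at the default 2–3-day
   half-life). Repliers who have already written more than 5 posts (the
   active core) additionally weight targets by
   (1 + target-author activity)^(−s), s = anti_richclub_strength
   (2.0 in the presets). Gating the bias to the core is deliberate:
   biasing *everyone* toward low-activity authors makes casual users
   seek each other out, which raises the mid-threshold rich-club ratio
   above 1 instead of producing the intended hub-to-periphery mixing.
5. **Follow-ups.** When a reply lands in a thread, with probability f
   (0.3 in the presets) the thread's root poster replies back to it
   after an exponential delay of mean 0.25 days. Follow-ups tie the root
   poster to repliers-of-repliers and are the generator's mechanism for
   closing triads; ramping f is how the triad analysis is validated.

All draws flow from one integer seed; the same config and seed give a
byte-identical log. Timestamps are microsecond-rounded offsets from a
fixed origin, which survives a CSV/JSONL round trip exactly.

**What the generator does not emulate:** post content and semantics,
user churn (join date is simply the first post; leave dates are unset),
community growth trends (the intensity is stationary apart from the
periodic modulation, so posts-per-user-per-week has no secular trend),
moderator behaviour (all synthetic authors have the `user` role), and
any coupling between a user's activity level and their answer share
(every base event draws root-vs-reply identically, so the
activity–expertise trend is near zero by construction in the presets —
recovering a positive trend is demonstrated on constructed logs
instead). Passing tests on synthetic data therefore validate the
*pipeline* — definitions, invariances, null models, recovery of
injected structure — not any claim about a particular real community.

## Problem sizes and numerical conventions

The bundled analyses and tests run the `blf_like` preset at ~13k posts /
2,000 posting users and `asthma_like` at ~8k posts / 525 posting users;
rich-club curves use 20 nulls (50 for the self-normalization control on
a 500-node heavy-tailed graph). These sizes put every Monte-Carlo
standard error well below the effects being measured while keeping a
full run in seconds. Ratios with zero denominators are flagged
undefined (NaN) rather than raised; comparisons of ρ against 1 in tests
allow 1e-9 of floating-point slack because the null mean of M identical
values need not be bit-identical to them. The acceptance script derives
every stage seed from its single `--seed` argument via SHA-256, so one
integer reproduces the whole computation.

## Known limitations

* The reply-to-parent-author convention is one of two defensible
  readings of "replied to a post by"; reply-to-root would yield
  systematically more star-like networks. The choice is isolated in
  `network_build` and documented there.
* The rich-club null uses a fixed swap budget (10·|E|) rather than a
  mixing-time diagnostic; for graphs with very constrained degree
  sequences the chain may underexplore the null space.
* The Bernoulli expertise model treats posts as exchangeable; bursty
  posting inflates |z| for prolific users relative to any model with
  per-user heterogeneity in the answer propensity.
* Interposting gaps pool across users, so the ECDF is dominated by the
  most prolific members of the selected set.
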