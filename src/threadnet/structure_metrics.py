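"""Component structure, targeted-removal sensitivity, and the
null-normalized rich-club coefficient.

The raw rich-club coefficient at threshold k is the edge density among
the users of degree >= k,

    R(k) = 2 E(S_k) / (|S_k| (|S_k| - 1)),   S_k = {v : deg(v) >= k},

undefined when fewer than two users reach the threshold. On its own R(k)
confounds club structure with the degree sequence, so it is normalized
by its mean over an ensemble of degree-preserving rewirings of the same
graph:

    rho(k) = R(k) / <R_rand(k)>.

rho > 1 indicates a rich club (hubs preferentially tied to each other);
rho < 1 an anti-rich-club regime where hubs preferentially answer the
poorly connected — the signature of help-giving cores in peer-support
communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError
from .model import PostLog
from .network_build import ReplyNetwork, UndirectedView


# ----------------------------------------------------------------------
# components

@dataclass
class ComponentPartition:
    """Partition of the node set into connected components."""

    components: list[frozenset]

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    @property
    def largest(self) -> frozenset:
        return max(self.components, key=len) if self.components else frozenset()

    @property
    def largest_size(self) -> int:
        return len(self.largest)


def connected_components(view: UndirectedView,
                         registry_nodes: set | None = None) -> ComponentPartition:
    """Undirected components; ``registry_nodes`` adds edge-less users as
    singleton components (each isolated user is its own component)."""
    g = view.graph
    if registry_nodes:
        g = g.copy()
        g.add_nodes_from(registry_nodes)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return ComponentPartition(components=comps)


def largest_component_fraction_series(
    log: PostLog, snapshots: list[tuple[int, ReplyNetwork]]
) -> pd.DataFrame:
    """Fraction of posting users inside the largest component, per week.

    The denominator at week k is the number of users who have posted by
    the end of that week (lurkers never enter it); users who posted but
    made no tie count as singleton components.
    """
    from .network_build import undirected_projection

    df = log.to_frame()
    rows = []
    for week, net in snapshots:
        bound = 7.0 * (week + 1)
        posters = set(df.loc[df["t_days"].values <= bound, "author_id"])
        if not posters:
            continue
        part = connected_components(undirected_projection(net), registry_nodes=posters)
        rows.append(
            {"week": week, "n_posting_users": len(posters),
             "largest_component_fraction": part.largest_size / len(posters)}
        )
    return pd.DataFrame(rows, columns=["week", "n_posting_users",
                                       "largest_component_fraction"])


# ----------------------------------------------------------------------
# targeted removal

@dataclass
class RemovalCurve:
    """Surviving largest-component fraction under targeted node removal."""

    fractions: np.ndarray
    values: np.ndarray
    n_nodes: int
    original_largest: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"removed_fraction": self.fractions,
                             "largest_component_fraction": self.values})


def targeted_removal_curve(view: UndirectedView,
                           fractions: list[float]) -> RemovalCurve:
    """Remove the top ceil(f * N) users by degree and report the surviving
    largest component as a fraction of the original largest component.

    The ranking is computed once on the intact graph (descending degree,
    ties broken by ascending user id) and is not recomputed adaptively.
    """
    g = view.graph
    n = g.number_of_nodes()
    if n == 0:
        raise EmptyInputError("cannot compute a removal curve on an empty network")
    ranked = sorted(g.nodes, key=lambda v: (-g.degree(v), v))
    original = max((len(c) for c in nx.connected_components(g)), default=0)
    values = []
    for f in fractions:
        k = math.ceil(f * n)
        survivor = g.subgraph(ranked[k:])
        largest = max((len(c) for c in nx.connected_components(survivor)), default=0)
        values.append(largest / original if original else 0.0)
    return RemovalCurve(
        fractions=np.asarray(fractions, dtype=float),
        values=np.asarray(values, dtype=float),
        n_nodes=n,
        original_largest=original,
    )


# ----------------------------------------------------------------------
# rich club

def rich_club_raw(view: UndirectedView, k: int) -> float | None:
    """Edge density among nodes of degree >= k; None when |S| < 2."""
    g = view.graph
    s = [v for v, d in g.degree() if d >= k]
    if len(s) < 2:
        return None
    e = g.subgraph(s).number_of_edges()
    return 2.0 * e / (len(s) * (len(s) - 1))


def _rich_club_curve_raw(view: UndirectedView, k_values: np.ndarray) -> np.ndarray:
    """Vectorized R(k) for many thresholds (NaN where undefined)."""
    g = view.graph
    deg = dict(g.degree())
    deg_arr = np.array(sorted(deg.values()))
    # per-edge minimum endpoint degree; an edge survives threshold k iff
    # both endpoints do, i.e. iff min degree >= k
    edge_min = np.array(sorted(min(deg[u], deg[v]) for u, v in g.edges()))
    out = np.full(len(k_values), np.nan)
    n = len(deg_arr)
    for i, k in enumerate(k_values):
        n_k = n - int(np.searchsorted(deg_arr, k, side="left"))
        if n_k < 2:
            continue
        e_k = len(edge_min) - int(np.searchsorted(edge_min, k, side="left"))
        out[i] = 2.0 * e_k / (n_k * (n_k - 1))
    return out


def degree_preserving_rewire(view: UndirectedView, n_swap_attempts: int,
                             seed: int | np.random.Generator) -> UndirectedView:
    """Randomize a graph by repeated double-edge swaps.

    Each attempt picks two distinct edges (u, v), (x, y) and proposes
    (u, x), (v, y) (with a random orientation of the second edge);
    proposals creating self-loops or multi-edges are rejected. The degree
    sequence is preserved exactly; the result is deterministic given the
    seed. Edge weights are not carried over (the null is unweighted).
    """
    g = view.graph
    m = g.number_of_edges()
    if m < 2:
        raise ConfigError("rewiring needs at least 2 edges")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = [tuple(sorted(e)) for e in g.edges()]
    edge_set = set(edges)

    idx = rng.integers(0, m, size=(n_swap_attempts, 2))
    flip = rng.integers(0, 2, size=n_swap_attempts)
    for a in range(n_swap_attempts):
        i, j = idx[a]
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if flip[a]:
            x, y = y, x
        # propose (u, x) and (v, y)
        if u == x or v == y:
            continue
        e1 = (u, x) if u < x else (x, u)
        e2 = (v, y) if v < y else (y, v)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2

    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    out.add_edges_from(edges, weight=1)
    return UndirectedView(graph=out)


@dataclass
class RichClubCurve:
    """Raw and null-normalized rich-club coefficients over a k grid."""

    k_values: np.ndarray
    raw: np.ndarray                 # R(k), NaN where undefined
    null_mean: np.ndarray
    null_std: np.ndarray
    normalized: np.ndarray          # rho(k), NaN where undefined
    n_nulls: int
    defined: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.defined = ~np.isnan(self.normalized)

    def max_defined(self) -> float:
        if not self.defined.any():
            raise EmptyInputError("no defined rich-club values on this grid")
        return float(np.nanmax(self.normalized))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k_values,
            "raw": self.raw,
            "null_mean": self.null_mean,
            "null_std": self.null_std,
            "normalized": self.normalized,
            "undefined": ~self.defined,
        })


def default_k_grid(view: UndirectedView) -> np.ndarray:
    """All observed degree values up to the 90th percentile degree."""
    degs = np.array(sorted(d for _, d in view.graph.degree()))
    if len(degs) == 0:
        return np.array([], dtype=int)
    cutoff = np.percentile(degs, 90)
    ks = np.unique(degs[degs <= cutoff])
    return ks.astype(int)


def normalized_rich_club_curve(
    view: UndirectedView,
    k_values=None,
    n_nulls: int = 20,
    n_swap_attempts: int | None = None,
    seed: int | np.random.Generator = 0,
) -> RichClubCurve:
    """rho(k) = R(k) / mean over ``n_nulls`` degree-preserving rewirings.

    ``n_swap_attempts`` defaults to 10x the edge count. Thresholds where
    fewer than two nodes qualify, or where the null mean is zero, are
    flagged undefined (NaN).
    """
    if n_nulls < 1:
        raise ConfigError("n_nulls must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k_values is None:
        k_values = default_k_grid(view)
    k_values = np.asarray(k_values, dtype=int)
    attempts = 10 * view.n_edges if n_swap_attempts is None else n_swap_attempts

    raw = _rich_club_curve_raw(view, k_values)
    nulls = np.empty((n_nulls, len(k_values)))
    for i in range(n_nulls):
        null_view = degree_preserving_rewire(view, attempts, rng)
        nulls[i] = _rich_club_curve_raw(null_view, k_values)
    null_mean = nulls.mean(axis=0)
    null_std = nulls.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(null_mean > 0, raw / null_mean, np.nan)
    return RichClubCurve(
        k_values=k_values,
        raw=raw,
        null_mean=null_mean,
        null_std=null_std,
        normalized=rho,
        n_nulls=n_nulls,
    )
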