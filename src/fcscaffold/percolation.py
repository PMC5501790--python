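"""Component-tracking percolation on a weighted network.

Links are removed one at a time in increasing weight order and the number of
connected components is recorded after every removal. Runs of removals that
leave the component count unchanged are *plateaux* (stable network
configurations); their lengths — the weight increment between consecutive
newborn-component events — are compared against a null ensemble to select
significance thresholds, avoiding any arbitrary binarisation of the
correlation matrix.

Component counts are computed with a reverse (edge-addition) union-find
sweep, which yields the count after every single removal in near-linear
time; a flood-fill recomputation serves as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


class _UnionFind:
    __slots__ = ("parent", "rank", "n_sets")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n
        self.n_sets = n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        self.n_sets -= 1
        return True


@dataclass
class PercolationCurve:
    """Ordered record of (removed-edge weight, component count after removal).

    ``initial_components`` is the count before any removal; the curve ends at
    N once every link is gone. Newborn events are the removals at which the
    count increased.
    """

    n_nodes: int
    initial_components: int
    weights_removed: np.ndarray
    n_components: np.ndarray

    def __post_init__(self) -> None:
        self.weights_removed = np.asarray(self.weights_removed, dtype=float)
        self.n_components = np.asarray(self.n_components, dtype=int)
        if len(self.n_components) and np.any(np.diff(self.n_components) < 0):
            raise ValueError("component count must be nondecreasing along removals")

    @property
    def newborn_events(self) -> tuple[np.ndarray, np.ndarray]:
        """(weights, counts) at removals where the component count increased."""
        prev = np.concatenate(([self.initial_components], self.n_components[:-1]))
        born = self.n_components > prev
        return self.weights_removed[born], self.n_components[born]

    @property
    def min_edge_weight(self) -> float:
        return float(self.weights_removed[0]) if len(self.weights_removed) else np.nan


@dataclass
class PlateauSet:
    """Plateau lengths of a percolation curve, one per component birth.

    ``lengths[k]`` is the weight increment between consecutive newborn
    events; the first plateau's left endpoint is the minimum edge weight of
    the graph. ``starts`` are the left endpoints (start-of-plateau weights)
    used as candidate thresholds; ``ends`` are the newborn-event weights;
    ``counts`` is the component count reached at each birth, which aligns
    plateaus across curves of the same size.
    """

    lengths: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        if self.counts is None:
            self.counts = np.arange(2, len(self.lengths) + 2)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.lengths < -1e-15):
            raise ValueError("plateau lengths must be nonnegative")


def rank_edges(w: np.ndarray) -> list[tuple[float, int, int]]:
    """All positive-weight edges as (weight, i, j), i<j, in increasing order.

    Ties are broken lexicographically by (i, j) so the removal order is a
    stable total order.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    keep = vals > 0
    edges = list(zip(vals[keep], iu[keep], ju[keep]))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    return [(float(v), int(i), int(j)) for v, i, j in edges]


def percolate(w: np.ndarray) -> PercolationCurve:
    """Remove links in increasing weight order, tracking component counts.

    Isolated nodes count as components; the curve therefore ends at N.
    Implemented as a reverse union-find sweep: edges are added from the top
    of the removal order downwards, and the recorded counts are read out in
    reverse.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    edges = rank_edges(w)
    m = len(edges)
    if m == 0:
        return PercolationCurve(n, n, np.empty(0), np.empty(0, dtype=int))
    uf = _UnionFind(n)
    counts = np.empty(m + 1, dtype=int)  # counts[k] = components after k removals
    counts[m] = n
    for k in range(m - 1, -1, -1):
        _, i, j = edges[k]
        uf.union(i, j)
        counts[k] = uf.n_sets
    weights = np.array([e[0] for e in edges])
    return PercolationCurve(
        n_nodes=n,
        initial_components=int(counts[0]),
        weights_removed=weights,
        n_components=counts[1:],
    )


def plateau_lengths(curve: PercolationCurve) -> PlateauSet:
    """Plateau lengths between consecutive newborn-component events.

    The first newborn event is paired with the global minimum edge weight, so
    the lengths telescope: they sum to (last newborn weight) - (min weight).
    """
    born_w, born_c = curve.newborn_events
    if len(born_w) == 0:
        return PlateauSet(np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=int))
    starts = np.concatenate(([curve.min_edge_weight], born_w[:-1]))
    lengths = born_w - starts
    return PlateauSet(lengths=lengths, starts=starts, ends=born_w, counts=born_c)


def null_plateau_stats(
    null_sets: list[PlateauSet], ddof: int = 1
) -> tuple[float, float, np.ndarray]:
    """Pooled mean, pooled SD, and per-curve mean lengths of a null ensemble."""
    pool = np.concatenate([p.lengths for p in null_sets]) if null_sets else np.empty(0)
    if pool.size == 0:
        raise ValueError("null ensemble contributed no plateau lengths")
    mu = float(pool.mean())
    sigma = float(pool.std(ddof=ddof)) if pool.size > ddof else 0.0
    per_curve = np.array([p.lengths.mean() if p.lengths.size else np.nan for p in null_sets])
    return mu, sigma, per_curve


def significant_plateaus(
    real: PlateauSet,
    null_ensemble: list[PlateauSet],
    k_sd: float = 4.0,
    method: str = "per_transition",
) -> np.ndarray:
    """Boolean mask of real plateaus whose length exceeds the null mean + k_sd SDs.

    ``method="per_transition"`` (default) compares each plateau against the
    null plateaus of the same component-count transition — the ensemble's
    mean + k_sd * SD band at that point of the curve. ``method="pooled"``
    compares every plateau against a single cut computed from all null
    plateau lengths pooled together; the pooled cut sits in the lower bulk of
    the heavily skewed length distribution, so it flags the longest plateau
    of nearly any curve, null curves included, and is kept only for
    reporting/comparison.
    """
    if len(null_ensemble) < 2:
        raise ValueError("need at least 2 null curves")
    if method == "pooled":
        mu, sigma, _ = null_plateau_stats(null_ensemble)
        return real.lengths > mu + k_sd * sigma
    if method != "per_transition":
        raise ValueError(f"unknown method {method!r}")
    if all(p.lengths.size == 0 for p in null_ensemble):
        raise ValueError("null ensemble contributed no plateau lengths")
    by_count: dict[int, list[float]] = {}
    for p in null_ensemble:
        for c, ln in zip(p.counts, p.lengths):
            by_count.setdefault(int(c), []).append(float(ln))
    mask = np.zeros(len(real.lengths), dtype=bool)
    for k, (c, ln) in enumerate(zip(real.counts, real.lengths)):
        vals = by_count.get(int(c))
        if vals is None or len(vals) < 2:
            continue
        arr = np.asarray(vals)
        mask[k] = ln > arr.mean() + k_sd * arr.std(ddof=1)
    return mask


def select_thresholds(
    real: PlateauSet,
    null_ensemble: list[PlateauSet],
    k_sd: float = 4.0,
    method: str = "per_transition",
) -> np.ndarray:
    """Start-of-plateau weights of the significantly long real plateaus.

    A real plateau is selected when its length strictly exceeds the null
    ensemble's mean + k_sd * SD (see :func:`significant_plateaus` for the two
    comparison methods). Returned sorted in decreasing weight order.
    """
    mask = significant_plateaus(real, null_ensemble, k_sd=k_sd, method=method)
    return np.sort(real.starts[mask])[::-1]


def snapshot_graph(
    w: np.ndarray, threshold: float, labels: list[str] | None = None
) -> nx.Graph:
    """The network retaining every link of weight >= threshold.

    All N nodes are always present; component membership and degree are
    attached as node attributes (``component``, ``degree``).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    g = nx.Graph()
    if labels is None:
        labels = [f"ROI{i + 1}" for i in range(n)]
    g.add_nodes_from(range(n))
    for i, lab in enumerate(labels):
        g.nodes[i]["label"] = lab
    iu, ju = np.triu_indices(n, k=1)
    keep = (w[iu, ju] >= threshold) & (w[iu, ju] > 0)
    g.add_weighted_edges_from(
        (int(i), int(j), float(w[i, j])) for i, j in zip(iu[keep], ju[keep])
    )
    for cid, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            g.nodes[node]["component"] = cid
    for node, deg in g.degree():
        g.nodes[node]["degree"] = deg
    return g
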