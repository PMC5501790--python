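"""Maximum Spanning Forest and Maximum Spanning Tree scaffold extraction.

The MSF keeps, for each node, only its single strongest link: a directed
network of exactly N arcs, each source pointing to its maximally correlated
partner. Its undirected support is a loop-free forest whose components are
the basal modules of the network; a chain-like component has nearly all
degrees <= 2, a star-like one a single high-degree hub. Completing the
forest with the heaviest inter-component links (union-find merging) yields
the Maximum Spanning Tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class SpanningForest:
    """Directed strongest-link forest: arc i -> argmax_j w_ij for every i."""

    arcs: list[tuple[int, int, float]]  # (source, target, weight)
    n_nodes: int
    components: list[set[int]] = field(init=False)
    reciprocated_pairs: set[frozenset[int]] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.arcs) != self.n_nodes:
            raise ValueError(f"{len(self.arcs)} arcs for {self.n_nodes} nodes")
        out = {s for s, _, _ in self.arcs}
        if out != set(range(self.n_nodes)):
            raise ValueError("every node must have out-degree exactly 1")
        pairs = {}
        for s, t, _ in self.arcs:
            pairs.setdefault(frozenset((s, t)), []).append(s)
        self.reciprocated_pairs = {p for p, srcs in pairs.items() if len(srcs) == 2}
        g = self.undirected_support()
        self.components = [set(c) for c in nx.connected_components(g)]

    def undirected_support(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for s, t, w in self.arcs:
            g.add_edge(s, t, weight=w)
        return g

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for _, t, _ in self.arcs:
            deg[t] += 1
        return deg


@dataclass
class SpanningTree:
    """Undirected maximum spanning tree: N-1 edges, connected, acyclic."""

    edges: list[tuple[int, int, float]]
    n_nodes: int

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError(f"{len(self.edges)} edges for {self.n_nodes} nodes")
        g = self.graph()
        if not nx.is_connected(g):
            raise ValueError("spanning tree is not connected")

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b, _ in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


@dataclass
class DegreeProfile:
    """Histogram of (in-)degrees plus the chain score.

    ``chain_score`` is the fraction of nodes whose undirected degree within
    their component is <= 2: 1.0 for pure paths, (m-1)/m for an m-node star.
    """

    counts: dict[int, int]
    fractions: dict[int, float]
    max_degree: int
    chain_score: float


def msf_rowmax(w: np.ndarray) -> SpanningForest:
    """Strongest-link filter: keep only the maximum-weight link of each row.

    Row ties are broken by the smallest partner index (self excluded). A row
    of all-equal weights still receives an arc by the tie rule, with a
    warning.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    arcs = []
    for i in range(n):
        row = w[i].copy()
        row[i] = -np.inf
        target = int(np.argmax(row))  # argmax takes the first (smallest) index on ties
        finite = np.delete(row, i)
        if np.all(finite == finite[0]):
            warnings.warn(f"row {i}: all weights equal; arc assigned by tie rule")
        arcs.append((i, target, float(w[i, target])))
    return SpanningForest(arcs=arcs, n_nodes=n)


def msf_greedy(w: np.ndarray) -> nx.Graph:
    """Build the forest from scratch: scan links in decreasing weight order,
    adding one whenever at least one endpoint still has degree zero; stop
    when every node is covered. Equivalent to the undirected support of the
    row-max filter whenever weights are distinct."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = sorted(zip(w[iu, ju], iu, ju), key=lambda e: (-e[0], e[1], e[2]))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    uncovered = n
    for val, i, j in order:
        if uncovered == 0:
            break
        di, dj = g.degree(int(i)), g.degree(int(j))
        if di == 0 or dj == 0:
            g.add_edge(int(i), int(j), weight=float(val))
            uncovered -= (di == 0) + (dj == 0)
    return g


def mst_complete(forest: SpanningForest, w: np.ndarray) -> SpanningTree:
    """Complete the forest to a Maximum Spanning Tree.

    The links not in the forest are scanned in decreasing weight order; a
    link is added when its endpoints lie in different components (union-find
    merging), until a single component spans all N nodes. With the forest
    built on the same weight matrix, the result attains the maximum spanning
    tree weight.
    """
    w = np.asarray(w, dtype=float)
    n = forest.n_nodes
    support = forest.undirected_support()
    edges = [(a, b, d["weight"]) for a, b, d in support.edges(data=True)]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in edges:
        parent[find(a)] = find(b)
    in_forest = {frozenset((a, b)) for a, b, _ in edges}
    iu, ju = np.triu_indices(n, k=1)
    candidates = sorted(
        (
            (w[i, j], int(i), int(j))
            for i, j in zip(iu, ju)
            if w[i, j] > 0 and frozenset((int(i), int(j))) not in in_forest
        ),
        key=lambda e: (-e[0], e[1], e[2]),
    )
    n_comp = len(forest.components)
    for val, i, j in candidates:
        if n_comp == 1:
            break
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, float(val)))
            n_comp -= 1
    if n_comp != 1:
        raise ValueError("weight matrix support is disconnected; cannot span all nodes")
    return SpanningTree(edges=edges, n_nodes=n)


def degree_profiles(structure: SpanningForest | nx.Graph | SpanningTree) -> DegreeProfile:
    """Degree histogram of a spanning structure.

    For a :class:`SpanningForest` the in-degree over all nodes is profiled
    (out-degree is 1 by construction, so in-degree 0 is possible and counted);
    for a tree or plain graph, the undirected degree. The chain score always
    refers to the undirected support.
    """
    if isinstance(structure, SpanningForest):
        deg = structure.in_degrees()
        support = structure.undirected_support()
    elif isinstance(structure, SpanningTree):
        support = structure.graph()
        deg = structure.degrees()
    else:
        support = structure
        deg = np.array([d for _, d in sorted(support.degree())], dtype=int)
    values, counts = np.unique(deg, return_counts=True)
    n = len(deg)
    undirected_deg = dict(support.degree())
    chain_score = sum(1 for d in undirected_deg.values() if d <= 2) / n
    return DegreeProfile(
        counts={int(v): int(c) for v, c in zip(values, counts)},
        fractions={int(v): float(c / n) for v, c in zip(values, counts)},
        max_degree=int(values.max()),
        chain_score=float(chain_score),
    )


def component_summary(
    forest: SpanningForest,
    roi_labels: list[str] | None = None,
    roi_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-component table: size, members, anatomical groups, reciprocation.

    ``roi_groups`` optionally maps ROI label -> anatomical group; absent
    labels leave the group column empty.
    """
    if roi_labels is None:
        roi_labels = [f"ROI{i + 1}" for i in range(forest.n_nodes)]
    support = forest.undirected_support()
    rows = []
    for comp in sorted(forest.components, key=lambda c: (-len(c), min(c))):
        members = sorted(comp)
        labels = [roi_labels[i] for i in members]
        groups = sorted({roi_groups.get(lab, "") for lab in labels} - {""}) if roi_groups else []
        degs = [support.degree(i) for i in members]
        recip = any(frozenset(p) <= comp for p in forest.reciprocated_pairs)
        rows.append(
            {
                "size": len(members),
                "members": ";".join(labels),
                "groups": ";".join(groups),
                "reciprocated": recip,
                "chain_score": sum(1 for d in degs if d <= 2) / len(members),
            }
        )
    return pd.DataFrame(rows)
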