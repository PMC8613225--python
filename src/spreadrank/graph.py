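"""Undirected simple graphs and their shortest-path structure.

The in-memory graph is the substrate for every centrality measure in this
package: node degrees carry the local information, geodesic (shortest-path)
hop counts carry the path information, and shortest-path multiplicities feed
betweenness. Graphs are simple and undirected throughout — duplicate edges
collapse and self-loops are dropped with a warning — and distances are
unweighted hop counts; pairs in different components are at ``UNREACHABLE``
(``math.inf``), a true sentinel so that inverse-square interaction terms are
exactly zero rather than merely small.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components as _csgraph_components
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

logger = logging.getLogger(__name__)

#: Sentinel distance for node pairs in different connected components.
UNREACHABLE = float("inf")


class Graph:
    """An undirected simple graph with string node labels.

    Parameters
    ----------
    labels : sequence of str
        Unique node identifiers. Order is preserved and defines the internal
        0-based indexing used by all matrix-valued results.
    edges : iterable of (str, str)
        Unordered adjacent pairs. Duplicates (in either orientation) collapse
        to a single edge; self-loops are dropped with a logged warning.
    """

    __slots__ = ("_labels", "_index", "_adj", "_m")

    def __init__(self, labels: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        labels = tuple(str(x) for x in labels)
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        self._labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        adj = np.zeros((n, n), dtype=np.uint8)
        dropped_loops = 0
        for a, b in edges:
            i, j = self.index(a), self.index(b)
            if i == j:
                dropped_loops += 1
                continue
            adj[i, j] = 1
            adj[j, i] = 1
        if dropped_loops:
            logger.warning("dropped %d self-loop(s); graphs are simple", dropped_loops)
        self._adj = adj
        self._m = int(np.triu(adj, 1).sum())

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] | None = None
    ) -> "Graph":
        """Build a graph from an edge iterable, inferring labels in first-seen
        order; ``nodes`` adds labels (e.g. isolated nodes) ahead of inference."""
        edges = [(str(a), str(b)) for a, b in edges]
        seen: dict[str, None] = {}
        for lab in nodes or ():
            seen.setdefault(str(lab), None)
        for a, b in edges:
            seen.setdefault(a, None)
            seen.setdefault(b, None)
        return cls(tuple(seen), edges)

    # -- basic accessors ---------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self._labels)

    @property
    def m(self) -> int:
        """Number of edges (unordered adjacent pairs)."""
        return self._m

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node label: {label!r}") from None

    def has_edge(self, a: str, b: str) -> bool:
        return bool(self._adj[self.index(a), self.index(b)])

    def neighbors(self, node: str) -> tuple[str, ...]:
        row = self._adj[self.index(node)]
        return tuple(self._labels[j] for j in np.flatnonzero(row))

    def degree(self, node: str) -> int:
        """Number of neighbors of ``node`` (degree centrality of one node)."""
        return int(self._adj[self.index(node)].sum())

    def degrees(self) -> np.ndarray:
        """Degree vector in label order."""
        return self._adj.sum(axis=1).astype(np.int64)

    def edges(self) -> list[tuple[str, str]]:
        """All edges as label pairs, each once, in index order."""
        ii, jj = np.nonzero(np.triu(self._adj, 1))
        return [(self._labels[i], self._labels[j]) for i, j in zip(ii, jj)]

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix (copy)."""
        return self._adj.copy()

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._labels)
        g.add_edges_from(self.edges())
        return g

    def subgraph(self, nodes: Iterable[str]) -> "Graph":
        keep = [lab for lab in self._labels if lab in set(nodes)]
        kset = set(keep)
        kept_edges = [(a, b) for a, b in self.edges() if a in kset and b in kset]
        return Graph(keep, kept_edges)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n={self.n}, m={self.m})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return set(self._labels) == set(other._labels) and {
            frozenset(e) for e in self.edges()
        } == {frozenset(e) for e in other.edges()}

    def __hash__(self):  # graphs are mutable-free but unhashable by policy
        raise TypeError("Graph is not hashable")


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs geodesic hop counts.

    ``values[i, j]`` is the length of the shortest path between nodes i and j
    (0 on the diagonal, ``UNREACHABLE`` across components).
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        idx = {lab: i for i, lab in enumerate(self.labels)}
        return float(self.values[idx[a], idx[b]])


@dataclass(frozen=True)
class GeodesicCounts:
    """Shortest-path multiplicities.

    ``sigma[m, n]`` is the number of distinct shortest paths between nodes m
    and n (``sigma[i, i] = 1`` by convention, 0 across components). The count
    of shortest m–n paths passing through an interior node i follows from the
    product rule ``sigma[m, i] * sigma[i, n]`` when i lies on a geodesic.
    """

    labels: tuple[str, ...]
    dist: np.ndarray
    sigma: np.ndarray
    _index: dict = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    def count(self, m: str, n: str) -> int:
        """Total number of shortest paths between m and n (p_mn)."""
        return int(self.sigma[self._index[m], self._index[n]])

    def count_through(self, m: str, n: str, i: str) -> int:
        """Number of shortest m–n paths with i as an interior node (p_mn(i))."""
        im, in_, ii = self._index[m], self._index[n], self._index[i]
        if ii in (im, in_):
            raise ValueError("interior node must differ from the endpoints")
        d = self.dist
        if not np.isfinite(d[im, in_]):
            return 0
        if d[im, ii] + d[ii, in_] != d[im, in_]:
            return 0
        return int(self.sigma[im, ii] * self.sigma[ii, in_])


def all_pairs_distances(graph: Graph) -> DistanceMatrix:
    """BFS hop counts between every pair of nodes."""
    if graph.n == 0:
        return DistanceMatrix(graph.labels, np.zeros((0, 0)))
    sparse = csr_array(graph.adjacency_matrix())
    d = _csgraph_shortest_path(sparse, method="D", directed=False, unweighted=True)
    return DistanceMatrix(graph.labels, d)


def geodesic_counts(graph: Graph) -> GeodesicCounts:
    """Shortest-path distance and multiplicity for every ordered pair.

    One BFS per source accumulates path counts along the shortest-path DAG:
    when the search first reaches a node at depth d+1, its count is the sum of
    the counts of its depth-d predecessors.
    """
    n = graph.n
    adj = graph.adjacency_matrix().astype(bool)
    dist = np.full((n, n), UNREACHABLE)
    sigma = np.zeros((n, n), dtype=np.float64)
    for s in range(n):
        dist[s, s] = 0.0
        sigma[s, s] = 1.0
        frontier = np.zeros(n, dtype=bool)
        frontier[s] = True
        depth = 0
        while frontier.any():
            depth += 1
            # path counts flowing one hop out of the current frontier
            flow = sigma[s] @ (adj & frontier[:, None])
            newly = (flow > 0) & ~np.isfinite(dist[s])
            dist[s, newly] = depth
            sigma[s, newly] = flow[newly]
            frontier = newly
    return GeodesicCounts(graph.labels, dist, sigma)


def connected_components(graph: Graph) -> list[list[str]]:
    """Partition of the labels into connected components (largest first,
    ties broken by smallest member index)."""
    if graph.n == 0:
        return []
    sparse = csr_array(graph.adjacency_matrix())
    k, member = _csgraph_components(sparse, directed=False)
    comps: list[list[str]] = [[] for _ in range(k)]
    for lab, c in zip(graph.labels, member):
        comps[c].append(lab)
    comps.sort(key=lambda c: (-len(c), graph.index(c[0])))
    return comps


def summary(graph: Graph) -> dict:
    """Headline network statistics: n, m, average degree, average distance.

    Average degree is 2m/n; average distance is the mean hop count over all
    unordered pairs of distinct reachable nodes. On a disconnected graph the
    mean is restricted to reachable pairs and flagged with ``connected=False``
    plus a logged warning.
    """
    n, m = graph.n, graph.m
    out = {
        "n": n,
        "m": m,
        "average_degree": (2.0 * m / n) if n else 0.0,
        "average_distance": float("nan"),
        "connected": True,
    }
    if n < 2:
        out["average_distance"] = 0.0
        return out
    d = all_pairs_distances(graph).values
    iu = np.triu_indices(n, 1)
    pair_d = d[iu]
    reachable = np.isfinite(pair_d)
    if not reachable.all():
        out["connected"] = False
        logger.warning(
            "graph is disconnected; average_distance restricted to reachable pairs"
        )
    out["average_distance"] = float(pair_d[reachable].mean()) if reachable.any() else float("nan")
    return out


def degree_histogram(graph: Graph):
    """Degree distribution: (mapping degree -> node count, per-node table).

    The second element is a list of ``(label, degree)`` pairs in label order;
    the probability version of the histogram is ``count / n``.
    """
    degs = graph.degrees()
    hist: dict[int, int] = {}
    for k in degs:
        hist[int(k)] = hist.get(int(k), 0) + 1
    table = list(zip(graph.labels, (int(k) for k in degs)))
    return hist, table
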