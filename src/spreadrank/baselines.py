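"""The six comparison centralities: degree, betweenness, closeness,
eigenvector, gravity, and eigenvector-weighted gravity.

All scores are raw (unnormalized) unless a definition requires otherwise;
method comparisons downstream are rank-based, so absolute scale is
immaterial there. The gravity measure scores node i as

    CG(i) = sum over reachable j != i of  k_i * k_j / d_ij^2

— the inverse-square interaction with degree playing the role of mass —
and the weighted variant multiplies CG(i) by the i-th entry of the
principal eigenvector of the adjacency matrix (unit Euclidean norm,
nonnegative entries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import Graph, DistanceMatrix, all_pairs_distances


@dataclass(frozen=True)
class CentralityResult:
    """Per-node scores from one centrality method."""

    method: str
    scores: dict
    params: dict = field(default_factory=dict)
    eigenvalue: float | None = None
    eigenvector: dict | None = None

    def ranking(self) -> list[str]:
        """Labels in descending score order, ties broken by ascending label."""
        return sorted(self.scores, key=lambda lab: (-self.scores[lab], lab))

    def as_array(self, labels) -> np.ndarray:
        return np.array([self.scores[lab] for lab in labels], dtype=float)


def degree_centrality(graph: Graph) -> CentralityResult:
    """DC: the number of neighbors of each node."""
    scores = {lab: float(k) for lab, k in zip(graph.labels, graph.degrees())}
    return CentralityResult("dc", scores)


def betweenness_centrality(graph: Graph) -> CentralityResult:
    """BC: for each node i, the sum over unordered pairs {m, n} (m, n != i)
    of the fraction of shortest m-n paths passing through i. Unnormalized."""
    bc = nx.betweenness_centrality(graph.to_networkx(), normalized=False)
    return CentralityResult("bc", {lab: float(bc[lab]) for lab in graph.labels})


def closeness_centrality(
    graph: Graph, variant: str = "classic", distances: DistanceMatrix | None = None
) -> CentralityResult:
    """CC: inverse sum of shortest distances to all other nodes.

    ``classic``: CC(i) = (n - 1) / sum_j d_ij, defined only on connected
    graphs. ``harmonic``: sum_j 1/d_ij with unreachable pairs contributing 0,
    defined everywhere.
    """
    if variant not in ("classic", "harmonic"):
        raise ValueError(f"unknown closeness variant: {variant!r}")
    d = (distances or all_pairs_distances(graph)).values
    n = graph.n
    scores = {}
    if variant == "classic":
        if n > 1 and not np.isfinite(d).all():
            raise ValueError(
                "classic closeness requires a connected graph; "
                "use variant='harmonic' for disconnected graphs"
            )
        for i, lab in enumerate(graph.labels):
            total = d[i].sum()
            scores[lab] = float((n - 1) / total) if total > 0 else 0.0
    else:
        with np.errstate(divide="ignore"):
            inv = np.where(d > 0, 1.0 / d, 0.0)
        inv[~np.isfinite(d)] = 0.0
        for i, lab in enumerate(graph.labels):
            scores[lab] = float(inv[i].sum())
    return CentralityResult("cc", scores, params={"variant": variant})


def eigenvector_centrality(
    graph: Graph, tol: float = 1e-10, max_iter: int = 1000
) -> CentralityResult:
    """EC: entries of the principal eigenvector of the adjacency matrix.

    Power iteration from a deterministic uniform start vector; the result is
    normalized to unit Euclidean norm with nonnegative entries (the Perron
    vector), and the dominant eigenvalue is recorded.
    """
    if graph.m == 0:
        raise ValueError("eigenvector centrality requires at least one edge")
    a = graph.adjacency_matrix().astype(float)
    n = graph.n
    # Iterate on A + I: same eigenvectors, but the dominant eigenvalue is
    # strictly separated in magnitude even on bipartite graphs, where raw
    # adjacency power iteration oscillates between +/- lambda_max.
    shifted = a + np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    for _ in range(max_iter):
        w = shifted @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("power iteration collapsed to zero vector")
        w /= norm
        if np.max(np.abs(w - v)) < tol:
            v = w
            lam = float(v @ (a @ v))
            break
        v = w
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge within {max_iter} iterations"
        )
    v = np.abs(v)  # Perron vector of a nonneg. matrix; sign fixed to +
    scores = {lab: float(x) for lab, x in zip(graph.labels, v)}
    return CentralityResult(
        "ec", scores, params={"tol": tol, "max_iter": max_iter},
        eigenvalue=lam, eigenvector=dict(scores),
    )


def gravity_interaction_matrix(
    graph: Graph, distances: DistanceMatrix | None = None
) -> np.ndarray:
    """Pairwise inverse-square interaction g_ij = k_i k_j / d_ij^2.

    Zero on the diagonal and for unreachable pairs (the interaction vanishes
    as distance grows without bound). Symmetric for undirected graphs.
    """
    d = (distances or all_pairs_distances(graph)).values
    k = graph.degrees().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.outer(k, k) / np.square(d)
    g[~np.isfinite(g)] = 0.0
    np.fill_diagonal(g, 0.0)
    return g


def gravity(graph: Graph, distances: DistanceMatrix | None = None) -> CentralityResult:
    """Gravity centrality: CG(i) = sum_j k_i k_j / d_ij^2 over reachable j."""
    g = gravity_interaction_matrix(graph, distances)
    scores = {lab: float(s) for lab, s in zip(graph.labels, g.sum(axis=1))}
    return CentralityResult("gravity", scores)


def weighted_gravity(
    graph: Graph, distances: DistanceMatrix | None = None
) -> CentralityResult:
    """Weighted gravity: WG(i) = e_i * CG(i), with e the unit-norm principal
    eigenvector of the adjacency matrix."""
    ec = eigenvector_centrality(graph)
    cg = gravity(graph, distances)
    scores = {lab: ec.scores[lab] * cg.scores[lab] for lab in graph.labels}
    return CentralityResult(
        "wgravity", scores, eigenvalue=ec.eigenvalue, eigenvector=ec.eigenvector
    )
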