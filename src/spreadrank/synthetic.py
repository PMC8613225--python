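"""Seeded synthetic graph generators and deterministic fixtures.

Every other module is testable without external downloads: the classic
random-graph families stand in for real contact networks, and a handful of
small hand-defined graphs with known symmetry serve as exact fixtures.

Conventions are pinned so the generated edge set is a pure function of the
spec (model, parameters, seed):

- ER (Erdős–Rényi G(n, p)): each unordered pair included independently.
- BA (Barabási–Albert): a complete-triangle seed core, then each arriving
  node attaches to ``m_attach`` distinct existing nodes sampled in
  proportion to their current degree, without replacement.
- WS (Watts–Strogatz): a ring lattice where each node connects to its
  ``k_ring`` nearest neighbors; each clockwise edge is rewired with
  probability ``p_rewire`` to a uniform new endpoint, resampling to avoid
  self-loops and duplicate edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import Graph


@dataclass(frozen=True)
class GenSpec:
    """A reproducible recipe for one synthetic graph."""

    model: str                      # er | ba | ws | fixture
    params: dict = field(default_factory=dict)
    rng_seed: int = 0


FIXTURE_NAMES = (
    "path3",
    "star4",
    "cycle5",
    "complete5",
    "two_stars_bridge",
    "grid4x4",
)


def fixture(name: str) -> Graph:
    """Hand-defined reference graphs.

    ``path3`` is the 3-node path a-b-c; ``star4`` is the star K1,3;
    ``two_stars_bridge`` joins two K1,4 stars by a single bridge edge, so
    every node has a mirror partner that must tie under any centrality.
    """
    if name == "path3":
        return Graph(("a", "b", "c"), [("a", "b"), ("b", "c")])
    if name == "star4":
        return Graph(("s", "a", "b", "c"), [("s", "a"), ("s", "b"), ("s", "c")])
    if name == "cycle5":
        labels = tuple(f"v{i}" for i in range(5))
        return Graph(labels, [(f"v{i}", f"v{(i + 1) % 5}") for i in range(5)])
    if name == "complete5":
        labels = tuple(f"v{i}" for i in range(5))
        return Graph(
            labels, [(f"v{i}", f"v{j}") for i in range(5) for j in range(i + 1, 5)]
        )
    if name == "two_stars_bridge":
        edges = [("h1", f"a{i}") for i in range(1, 5)]
        edges += [("h2", f"b{i}") for i in range(1, 5)]
        edges.append(("h1", "h2"))
        labels = ("h1", "h2") + tuple(f"a{i}" for i in range(1, 5)) + tuple(
            f"b{i}" for i in range(1, 5)
        )
        return Graph(labels, edges)
    if name == "grid4x4":
        labels = tuple(f"r{i}c{j}" for i in range(4) for j in range(4))
        edges = []
        for i in range(4):
            for j in range(4):
                if j < 3:
                    edges.append((f"r{i}c{j}", f"r{i}c{j + 1}"))
                if i < 3:
                    edges.append((f"r{i}c{j}", f"r{i + 1}c{j}"))
        return Graph(labels, edges)
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")


def _er(n: int, p: float, rng: np.random.Generator) -> Graph:
    if n < 1:
        raise ValueError("er: n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("er: p must be in [0, 1]")
    labels = tuple(str(i) for i in range(n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(iu[0].size) < p
    edges = [(labels[i], labels[j]) for i, j in zip(iu[0][mask], iu[1][mask])]
    return Graph(labels, edges)


def _ba(n: int, m_attach: int, rng: np.random.Generator) -> Graph:
    if m_attach < 1:
        raise ValueError("ba: m_attach must be >= 1")
    if n < 3 or m_attach >= n:
        raise ValueError("ba: need n >= 3 and m_attach < n")
    labels = tuple(str(i) for i in range(n))
    edges = [(0, 1), (0, 2), (1, 2)]  # complete-triangle seed core
    degree = np.zeros(n, dtype=np.int64)
    degree[:3] = 2
    for new in range(3, n):
        k = min(m_attach, new)
        weights = degree[:new].astype(float)
        targets = rng.choice(new, size=k, replace=False, p=weights / weights.sum())
        for t in targets:
            edges.append((int(t), new))
            degree[t] += 1
        degree[new] = k
    return Graph(labels, [(labels[a], labels[b]) for a, b in edges])


def _ws(n: int, k_ring: int, p_rewire: float, rng: np.random.Generator) -> Graph:
    if k_ring < 2 or k_ring % 2 or k_ring >= n:
        raise ValueError("ws: k_ring must be even, >= 2 and < n")
    if not 0.0 <= p_rewire <= 1.0:
        raise ValueError("ws: p_rewire must be in [0, 1]")
    labels = tuple(str(i) for i in range(n))
    edge_set: set[frozenset[int]] = set()
    for i in range(n):
        for j in range(1, k_ring // 2 + 1):
            edge_set.add(frozenset((i, (i + j) % n)))
    # rewire each clockwise lattice edge in a fixed scan order
    for i in range(n):
        for j in range(1, k_ring // 2 + 1):
            old = frozenset((i, (i + j) % n))
            if old not in edge_set or rng.random() >= p_rewire:
                continue
            for _ in range(10 * n):  # resample to avoid loops and duplicates
                t = int(rng.integers(n))
                new = frozenset((i, t))
                if t != i and new not in edge_set:
                    edge_set.discard(old)
                    edge_set.add(new)
                    break
    edges = [tuple(sorted(e)) for e in edge_set]
    return Graph(labels, [(labels[a], labels[b]) for a, b in sorted(edges)])


def generate(spec: GenSpec) -> Graph:
    """Generate a graph from a :class:`GenSpec`; deterministic in rng_seed."""
    rng = np.random.default_rng(spec.rng_seed)
    p = spec.params
    if spec.model == "er":
        return _er(int(p["n"]), float(p["p"]), rng)
    if spec.model == "ba":
        return _ba(int(p["n"]), int(p["m_attach"]), rng)
    if spec.model == "ws":
        return _ws(int(p["n"]), int(p["k_ring"]), float(p["p_rewire"]), rng)
    if spec.model == "fixture":
        return fixture(p["name"])
    raise ValueError(f"unknown model {spec.model!r}; choose er, ba, ws or fixture")
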