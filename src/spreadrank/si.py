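"""Discrete-time susceptible-infected (SI) epidemic simulation.

The SI process is the ground truth against which centrality rankings are
judged: a node's spreading capacity is the mean number of infected nodes
(seed included) after a fixed horizon when the epidemic starts at that node.

Dynamics are synchronous: at each step every currently infectious node
independently attempts to infect each of its susceptible neighbors with
probability ``beta``; nodes infected at step t become infectious at step
t+1, and nobody recovers. A susceptible node with ``c`` infectious
neighbors is therefore infected with probability ``1 - (1 - beta)^c``,
which is how the update is vectorized.

Every run draws from its own RNG stream derived from
``(rng_seed, seed-node index, run index)``, so results are reproducible and
independent of iteration order.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

from .graph import Graph


@dataclass(frozen=True)
class SIConfig:
    """Simulation parameters.

    beta : per infected-susceptible contact, per step infection probability.
    steps : number of synchronous update steps (the simulation horizon).
    runs : independent repetitions per seed node.
    rng_seed : master seed; every (seed node, run) stream derives from it.
    """

    beta: float
    steps: int
    runs: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.rng_seed < 0:
            raise ValueError("rng_seed must be nonnegative")


@dataclass(frozen=True)
class SpreadResult:
    """Cumulative infected-count time series per seed node.

    ``series[seed]`` has shape (runs, steps + 1); entry [r, t] is the number
    of infected nodes after t steps of run r (t = 0 is the initial state,
    always 1). ``capacity`` is the mean over runs of the final count — the
    "average infected nodes" spreading capacity.
    """

    config: SIConfig
    series: dict

    def mean_curve(self, seed: str) -> np.ndarray:
        return self.series[seed].mean(axis=0)

    @property
    def capacity(self) -> dict:
        return {seed: float(s[:, -1].mean()) for seed, s in self.series.items()}


def _rng(config: SIConfig, node_index: int, run_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config.rng_seed, node_index, run_index))
    )


def si_run(
    graph: Graph, seed_node: str, config: SIConfig, run_index: int = 0
) -> np.ndarray:
    """One SI trajectory; returns the cumulative infected counts, length
    ``steps + 1`` with entry 0 equal to 1 (the seed alone)."""
    i0 = graph.index(seed_node)
    adj = graph.adjacency_matrix()
    rng = _rng(config, i0, run_index)
    n = graph.n
    infected = np.zeros(n, dtype=bool)
    infected[i0] = True
    counts = np.empty(config.steps + 1, dtype=np.int64)
    counts[0] = 1
    beta = config.beta
    for t in range(1, config.steps + 1):
        contacts = adj @ infected  # infectious-neighbor count per node
        at_risk = (~infected) & (contacts > 0)
        if at_risk.any() and beta > 0.0:
            p = 1.0 - (1.0 - beta) ** contacts[at_risk]
            hits = rng.random(int(at_risk.sum())) < p
            infected[np.flatnonzero(at_risk)[hits]] = True
        counts[t] = int(infected.sum())
    return counts


def simulate(graph: Graph, seeds: Sequence[str], config: SIConfig) -> SpreadResult:
    """Run ``config.runs`` SI trajectories from each seed node."""
    series = {}
    for seed in seeds:
        rows = np.stack(
            [si_run(graph, seed, config, run_index=r) for r in range(config.runs)]
        )
        series[seed] = rows
    return SpreadResult(config, series)


def spreading_capacity(
    graph: Graph, nodes: Iterable[str] | None, config: SIConfig
) -> dict:
    """Mean final infected count per seed node (seed included in the count)."""
    seeds = list(nodes) if nodes is not None else list(graph.labels)
    return simulate(graph, seeds, config).capacity


def topk_average_curve(
    graph: Graph, ranking: Sequence[str], k: int, config: SIConfig
) -> np.ndarray:
    """Summed mean infection curves of the top-k ranked nodes.

    For each of the first k labels of ``ranking``, the per-node mean curve
    over runs is computed; the k mean curves are summed pointwise. This is
    the cumulative "average infected nodes of the top k" trajectory used to
    compare how well different rankings pick out strong spreaders.
    """
    if k > graph.n:
        raise ValueError(f"k={k} exceeds node count {graph.n}")
    top = list(ranking)[:k]
    result = simulate(graph, top, config)
    return np.sum([result.mean_curve(seed) for seed in top], axis=0)
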