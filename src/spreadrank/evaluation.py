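"""Rank agreement between centrality scores and SI spreading capacity.

Kendall's tau counts concordant minus discordant pairs of the two score
sequences. Three denominators are provided:

- ``tau_a``: n(n-1)/2, the number of unordered pairs — the textbook tau-a;
- ``tau_b``: the tie-corrected denominator (the default here, because both
  capacities and several centralities contain ties);
- ``tau_half``: n(n-1), a variant whose range is [-1/2, 1/2]; it equals
  tau_a / 2 exactly on tie-free data.

Ties contribute to neither count in any variant.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import baselines
from .dematel import rank_dematel
from .graph import Graph, all_pairs_distances
from .si import SIConfig, spreading_capacity

logger = logging.getLogger(__name__)

VARIANTS = ("tau_b", "tau_a", "tau_half")


@dataclass(frozen=True)
class TauResult:
    """Kendall rank correlation with its pair counts."""

    tau: float
    concordant: int
    discordant: int
    n: int
    variant: str


def kendall_tau(
    x: Sequence[float], y: Sequence[float], variant: str = "tau_b"
) -> TauResult:
    """Kendall rank correlation between two equal-length sequences.

    A pair (i, j) is concordant when (x_i - x_j)(y_i - y_j) > 0 and
    discordant when < 0; ties count as neither. The ``variant`` selects the
    denominator (see module docstring). With an all-tied sequence, tau_b's
    denominator vanishes and NaN is returned with a warning.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")

    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    iu = np.triu_indices(n, 1)
    upper = prod[iu]
    concordant = int((upper > 0).sum())
    discordant = int((upper < 0).sum())
    num = concordant - discordant
    pairs = n * (n - 1) // 2

    if variant == "tau_half":
        denom = float(n * (n - 1))
    elif variant == "tau_a":
        denom = float(pairs)
    else:  # tau_b
        ties_x = int((sx[iu] == 0).sum())
        ties_y = int((sy[iu] == 0).sum())
        denom = float(np.sqrt((pairs - ties_x) * (pairs - ties_y)))
        if denom == 0.0:
            warnings.warn(
                "tau_b undefined: at least one sequence is entirely tied",
                RuntimeWarning,
                stacklevel=2,
            )
            return TauResult(float("nan"), concordant, discordant, n, variant)
    return TauResult(num / denom, concordant, discordant, n, variant)


def _dematel_result(graph: Graph) -> baselines.CentralityResult:
    _, imp = rank_dematel(graph)
    return baselines.CentralityResult("dematel-gravity", imp.scores)


#: Registry of ranking methods by their CLI names.
METHODS = {
    "dc": baselines.degree_centrality,
    "bc": baselines.betweenness_centrality,
    "cc": baselines.closeness_centrality,
    "ec": baselines.eigenvector_centrality,
    "gravity": baselines.gravity,
    "wgravity": baselines.weighted_gravity,
    "dematel-gravity": _dematel_result,
}


def compute_centrality(graph: Graph, method: str) -> baselines.CentralityResult:
    """Score all nodes with one registered method (see ``METHODS``)."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(METHODS)}"
        ) from None
    return fn(graph)


def correlation_experiment(
    graph: Graph,
    methods: Sequence[str],
    beta_grid: Sequence[float],
    steps: int = 20,
    runs: int = 100,
    rng_seed: int = 0,
    variant: str = "tau_b",
) -> pd.DataFrame:
    """Kendall tau between each method's scores and SI spreading capacity,
    across an infection-probability grid.

    For each beta, capacities for every node are simulated once and shared
    by all methods. Returns a long DataFrame with columns
    ``method, beta, tau``. Betas at which all capacities coincide (e.g.
    beta = 0, or beta = 1 with a long horizon on a connected graph) produce
    NaN tau with a warning.
    """
    results = {m: compute_centrality(graph, m) for m in methods}
    labels = list(graph.labels)
    rows = []
    for beta in beta_grid:
        cfg = SIConfig(beta=float(beta), steps=steps, runs=runs, rng_seed=rng_seed)
        cap = spreading_capacity(graph, labels, cfg)
        cap_vec = np.array([cap[lab] for lab in labels])
        for m in methods:
            score_vec = results[m].as_array(labels)
            tau = kendall_tau(score_vec, cap_vec, variant=variant).tau
            rows.append({"method": m, "beta": float(beta), "tau": tau})
    return pd.DataFrame(rows, columns=["method", "beta", "tau"])


def top_table(
    results: Sequence[baselines.CentralityResult], k: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k node labels per method, plus pairwise top-k overlap counts.

    Returns ``(table, overlap)``: ``table`` has one column per method and
    rows rank 1..k; ``overlap[a, b]`` is the number of labels the two
    methods share among their respective top k.
    """
    if not results:
        raise ValueError("need at least one centrality result")
    n = len(results[0].scores)
    if k > n:
        raise ValueError(f"k={k} exceeds node count {n}")
    cols = {}
    for res in results:
        cols[res.method] = res.ranking()[:k]
    table = pd.DataFrame(cols, index=pd.RangeIndex(1, k + 1, name="rank"))
    names = list(cols)
    overlap = pd.DataFrame(
        [[len(set(cols[a]) & set(cols[b])) for b in names] for a in names],
        index=names,
        columns=names,
    )
    return table, overlap
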