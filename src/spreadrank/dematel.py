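"""The DEMATEL-gravity model: node importance from total (direct + indirect)
pairwise influence.

The pipeline:

1. Direct relation matrix ``D`` with entries ``g_ij = k_i k_j / d_ij^2`` —
   the inverse-square gravity interaction between nodes i and j (zero on the
   diagonal and across components).
2. Normalize by a single global scalar ``s`` — the larger of the maximum row
   sum and maximum column sum of ``D`` — giving ``Nm = D / s``.
3. Total relation matrix ``T = Nm + Nm^2 + Nm^3 + ...``: each matrix power
   adds one more level of indirect influence transmitted through
   intermediaries. When the spectral radius of ``Nm`` is below 1 the series
   has the closed form ``T = Nm (I - Nm)^{-1}``; otherwise a truncated
   partial sum is used (see :func:`total_relation_matrix`).
4. ``R_i`` (row sums of ``T``) is the total influence node i exerts, ``C_i``
   (column sums) the total influence it receives, and the importance score
   is ``a_i = R_i + C_i``. For an undirected graph ``T`` is symmetric, so
   ``R = C`` and ``a = 2R``.

The normalization scalar is exactly what makes step 3 meaningful: dividing
by the largest row/column sum bounds the spectral radius of ``Nm`` by 1, so
the influence transmitted along ever-longer chains (usually) decays and the
series (usually) converges. The boundary case — spectral radius exactly 1,
which occurs for vertex-transitive interaction matrices such as cycles and
complete graphs — is handled by the truncated series with a warning; the
partial sums preserve the symmetry structure, so rankings remain meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .baselines import gravity_interaction_matrix
from .graph import Graph, DistanceMatrix, all_pairs_distances

logger = logging.getLogger(__name__)

#: Spectral-radius margin below 1 required to use the closed-form inverse.
_RHO_MARGIN = 1e-9


@dataclass(frozen=True)
class RelationMatrices:
    """The three matrices of the pipeline plus the normalization scale."""

    labels: tuple
    direct: np.ndarray       # D, entries g_ij
    normalized: np.ndarray   # Nm = D / scale
    total: np.ndarray        # T = sum of powers of Nm
    scale: float             # s, the normalization denominator
    method: str              # "closed_form" | "truncated_series"


@dataclass(frozen=True)
class ImportanceResult:
    """Node importance a = R + C with the derived ranking."""

    labels: tuple
    r: np.ndarray
    c: np.ndarray
    importance: np.ndarray
    method: str = "dematel-gravity"

    @property
    def scores(self) -> dict:
        return {lab: float(a) for lab, a in zip(self.labels, self.importance)}

    def ranking(self) -> list[str]:
        """Labels in descending importance, ties broken by ascending label."""
        s = self.scores
        return sorted(s, key=lambda lab: (-s[lab], lab))


def direct_relation_matrix(
    graph: Graph, distances: DistanceMatrix | None = None
) -> np.ndarray:
    """Gravity direct-relation matrix D with g_ij = k_i k_j / d_ij^2."""
    return gravity_interaction_matrix(graph, distances)


def normalize_relation_matrix(d: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale D by s = max(max row sum, max column sum); returns (Nm, s).

    An all-zero D (edgeless graph) has s = 0 and is returned unchanged.
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("direct relation matrix must be nonnegative")
    s = float(max(d.sum(axis=1).max(initial=0.0), d.sum(axis=0).max(initial=0.0)))
    if s == 0.0:
        return d.copy(), 0.0
    return d / s, s


def spectral_radius(m: np.ndarray, tol: float = 1e-10, max_iter: int = 10000) -> float:
    """Largest absolute eigenvalue of ``|m|``, by power iteration."""
    a = np.abs(np.asarray(m, dtype=float))
    n = a.shape[0]
    if n == 0 or not a.any():
        return 0.0
    # shift keeps the iteration from oscillating on bipartite-like structure
    shifted = a + np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = shifted @ v
        w /= np.linalg.norm(w)
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    return float(v @ (a @ v))


def total_relation_matrix(
    nm: np.ndarray,
    mode: str = "auto",
    tol: float = 1e-12,
    max_terms: int = 1000,
) -> tuple[np.ndarray, str]:
    """Total relation matrix T = sum_{k>=1} Nm^k; returns (T, method tag).

    ``mode='auto'`` uses the closed form ``Nm (I - Nm)^{-1}`` when the
    spectral radius of Nm is safely below 1, and otherwise falls back to the
    truncated partial sum; ``'closed_form'`` and ``'series'`` force a route.
    The series accumulates powers until the largest entrywise increment drops
    below ``tol`` or ``max_terms`` terms are summed, warning when it stops on
    the term budget (the degenerate spectral-radius-1 case).
    """
    nm = np.asarray(nm, dtype=float)
    if not np.isfinite(nm).all():
        raise FloatingPointError("normalized relation matrix has non-finite entries")
    if mode not in ("auto", "closed_form", "series"):
        raise ValueError(f"unknown mode: {mode!r}")

    use_closed = mode == "closed_form"
    if mode == "auto":
        use_closed = spectral_radius(nm) < 1.0 - _RHO_MARGIN
    if use_closed:
        n = nm.shape[0]
        t = nm @ np.linalg.inv(np.eye(n) - nm)
        if not np.isfinite(t).all():
            raise FloatingPointError("closed-form total relation matrix is non-finite")
        return t, "closed_form"

    t = np.zeros_like(nm)
    power = nm.copy()
    for _ in range(max_terms):
        t += power
        increment = np.max(np.abs(power))
        if increment < tol:
            break
        power = power @ nm
    else:
        logger.warning(
            "total-relation series not converged after %d terms "
            "(spectral radius at or above 1); using the partial sum",
            max_terms,
        )
    if not np.isfinite(t).all():
        raise FloatingPointError("total relation series diverged to non-finite values")
    return t, "truncated_series"


def causal_parameters(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row sums R (influence exerted) and column sums C (influence received)."""
    t = np.asarray(t, dtype=float)
    return t.sum(axis=1), t.sum(axis=0)


def rank_dematel(
    graph: Graph,
    distances: DistanceMatrix | None = None,
    mode: str = "auto",
    tol: float = 1e-12,
    max_terms: int = 1000,
) -> tuple[RelationMatrices, ImportanceResult]:
    """Run the full DEMATEL-gravity pipeline on a graph.

    Returns the intermediate matrices and the importance result whose score
    for node i is a_i = R_i + C_i.
    """
    if graph.n < 2:
        raise ValueError("DEMATEL-gravity needs at least 2 nodes")
    if distances is None:
        distances = all_pairs_distances(graph)
    d = direct_relation_matrix(graph, distances)
    nm, scale = normalize_relation_matrix(d)
    t, method = total_relation_matrix(nm, mode=mode, tol=tol, max_terms=max_terms)
    r, c = causal_parameters(t)
    matrices = RelationMatrices(graph.labels, d, nm, t, scale, method)
    result = ImportanceResult(graph.labels, r, c, r + c)
    return matrices, result
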