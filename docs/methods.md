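# Methods

## Model

`spreadrank` scores node importance on an undirected simple graph
G = (V, E), |V| = n, by total pairwise influence. The direct influence of
node i on node j is the gravity interaction g_ij = k_i k_j / d_ij², where
k is degree and d_ij the geodesic hop count; the diagonal is zero, and
pairs in different components have zero direct influence (the interaction
vanishes as distance grows without bound, and the unreachable sentinel is
infinity, never a large finite number). The matrix D = (g_ij) is
normalized by a single global scalar s — the larger of the maximum row sum
and the maximum column sum — to N = D/s, and total influence accumulates
the Neumann series T = Σ_{p≥1} Nᵖ: the p-th power carries influence
transmitted through chains of p−1 intermediaries. Importance is
a_i = R_i + C_i with R the row sums and C the column sums of T.

Assumptions inherited from this construction: the network is undirected,
unweighted and simple (edge weights in input files are ignored; arcs are
symmetrized; duplicate edges collapse; self-loops are dropped with a
warning); influence decays with the inverse square of hop distance; and
indirect influence composes multiplicatively along chains.

## Numerical choices

- **Series vs closed form.** Because the row sums of N are at most 1, the
  spectral radius ρ(N) ≤ 1. When ρ(N) < 1 − 1e−9 (estimated by power
  iteration with tolerance 1e−10), T is evaluated as N(I − N)⁻¹.
  Otherwise — which happens exactly when the interaction matrix is
  "regular enough" that every row attains the maximum sum, e.g. on cycles,
  complete graphs and other vertex-transitive graphs — the closed form is
  singular, and T falls back to the truncated partial sum (tolerance
  1e−12 on the largest entrywise increment, at most 1000 terms) with a
  logged warning. Partial sums preserve the symmetry structure, so
  automorphism-equivalent nodes still tie and rankings remain meaningful;
  absolute score magnitudes in this degenerate regime depend on the term
  budget and should not be compared across graphs.
- **Eigenvector centrality** is computed by power iteration on A + I from
  a uniform start vector (tolerance 1e−10 on the max-abs iterate change,
  budget 1000 iterations, error on exhaustion). The identity shift leaves
  the eigenvectors unchanged while separating the dominant eigenvalue in
  magnitude; raw adjacency iteration oscillates on bipartite graphs (stars,
  paths, even cycles). The result is the Perron choice: nonnegative
  entries, unit Euclidean norm; the dominant eigenvalue is the Rayleigh
  quotient at convergence.
- **Closeness** has two variants: classic CC(i) = (n−1)/Σ_j d_ij (errors
  on disconnected graphs, pointing to the alternative) and harmonic
  Σ_j 1/d_ij with unreachable pairs contributing 0.
- **Betweenness** counts each unordered pair once, excludes endpoints, and
  is not normalized; it delegates to the Brandes implementation in
  networkx and is cross-checked in the tests against exhaustive
  shortest-path enumeration and against this package's own
  geodesic-count accumulation.
- **Ties.** All rankings break score ties by ascending node label, so every
  output is deterministic. Score tables use dense 1-based ranks. Note that
  scores of automorphism-equivalent nodes can differ in the last floating
  bit (different summation orders), which matters only when exact tie
  structure is inspected.

## SI simulation

Discrete synchronous time: at each step, every infectious node
independently infects each susceptible neighbor with probability β; newly
infected nodes become infectious the next step; there is no recovery. The
vectorized update infects a susceptible node with c infectious neighbors
with probability 1 − (1 − β)^c, which is exactly the independent
per-contact rule. A node's spreading capacity is the mean over runs of the
final cumulative infected count, **seed included** (all nodes in state I
are counted); including the seed shifts every capacity by exactly 1 and no
ranking. The "simulation time" parameter is the number of synchronous
steps. Default experiment settings follow the conventions of this
problem's literature: β = 0.1 with 10 runs for capacity curves (horizon
45), and a 20-step horizon with 100 runs for the tau-vs-β experiment with
a β grid from 0.05 to 1.0 in steps of 0.05 (β = 0 is excluded by default
because every capacity is then 1 and rank correlation is undefined).

Every run draws from an RNG stream seeded by the tuple
(master seed, seed-node index, run index), so results are byte-identical
across reruns and independent of iteration order or parallel scheduling.

## Rank evaluation

Kendall's tau counts concordant minus discordant pairs; ties count as
neither. Variants: tau-a (denominator n(n−1)/2), tau-b (tie-corrected,
the default because capacities and several centralities contain ties; NaN
with a warning when a sequence is entirely tied), and a historical variant
with denominator n(n−1), whose range is [−½, ½] and which equals tau-a/2
exactly on tie-free data. Variant choice rescales tau but never reorders
methods, since all variants share the numerator.

## Synthetic data

The generators provide the study conditions for all tests, because the
classic benchmark contact networks are distributed externally and are not
redistributed here. Conventions are pinned so a (model, parameters, seed)
triple is reproducible byte-for-byte:

- **ER** G(n, p): each unordered pair independently with probability p.
- **BA**: complete-triangle seed core; each arriving node attaches to
  m_attach distinct existing nodes sampled degree-proportionally without
  replacement. Edge count is exactly 3 + m_attach·(n − 3) for
  m_attach ≤ 3.
- **WS**: ring lattice with k_ring nearest neighbors; each clockwise
  lattice edge rewires with probability p_rewire, resampling to avoid
  self-loops and duplicates (edge count is preserved).

The stand-in for a musician-collaboration network used in the qualitative
top-50 experiment is a BA graph with n = 198, m_attach = 14 (mean degree
≈ 26.9, matching the real network's ≈ 27.7). It reproduces the scale,
right-skewed degree distribution and short distances, but **not** the
community structure, degree assortativity or clustering of a real
collaboration network — so tests passing on it show that the pipeline
discriminates spreaders under heavy-tailed degree heterogeneity, not that
relative method performance transfers to any particular real network. The
acceptance script accordingly measures tau in the epidemic's growth phase
(4 steps at β = 0.1): on a graph this dense the infection saturates within
a few steps, after which capacities stop discriminating between seeds and
tau is undefined.

## Problem sizes

Tests and the acceptance script use graphs up to n = 200 and at most a few
hundred SI runs per configuration — sizes chosen so the whole suite
completes in well under a minute on one core while the stochastic checks
(binomial expectation on a star with 10⁴ runs, monotonicity in β with 500
runs) still have standard errors an order of magnitude below the asserted
margins. All matrix work is dense; the intended regime is networks of up
to a few thousand nodes.

## Known limitations

- Directed or weighted influence is out of scope; input weights are
  discarded.
- Dense n×n matrices bound practical size (memory grows as n²).
- In the ρ(N) = 1 degenerate regime, importance magnitudes depend on the
  series truncation; only ranks are meaningful.
- The classic closeness variant is undefined on disconnected graphs by
  construction; use the harmonic variant there.
- SI capacity saturates on dense graphs at moderate β and long horizons,
  making every seed equivalent; choose the horizon in the growth phase
  when using capacity as ground truth.
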