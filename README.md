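# spreadrank

Identifying influential spreaders in complex networks — which nodes, if they
started an epidemic, a rumor, or a cascade, would reach the most of the
network? `spreadrank` implements a DEMATEL-gravity importance model that
combines local information (degree), path information (geodesic distance)
and global information (indirect influence transmitted through chains of
intermediaries), alongside six classic centralities, a
susceptible–infected (SI) epidemic simulator that provides the ground-truth
spreading capacity, and a Kendall-tau evaluation harness for comparing
rankings against that ground truth. It is aimed at network scientists and
systems biologists benchmarking super-spreader identification on contact
networks.

## The model

For an undirected simple graph with degrees `k_i` and geodesic hop
distances `d_ij`, the pairwise **direct influence** is the inverse-square
gravity interaction

    g_ij = k_i k_j / d_ij^2        (0 on the diagonal and across components)

collected in the direct relation matrix `D`. Normalizing by the single
scalar `s = max(max_i Σ_j g_ij, max_j Σ_i g_ij)` gives `N = D/s`, whose
spectral radius is at most 1. The **total relation matrix** adds indirect
influence along chains of every length:

    T = N + N² + N³ + ... = N (I − N)⁻¹    (when the series converges)

Row sums `R_i = Σ_j t_ij` measure influence exerted, column sums
`C_i = Σ_j t_ji` influence received, and node importance is

    a_i = R_i + C_i .

For undirected graphs `T` is symmetric, so `R = C` and `a = 2R`. When the
spectral radius of `N` equals 1 (vertex-transitive interaction structure,
e.g. cycles), the closed form is replaced by a truncated series with a
warning; rankings remain meaningful because partial sums preserve the
symmetry.

Baselines: degree (DC), betweenness (BC), closeness (CC), eigenvector (EC),
gravity `CG(i) = Σ_j k_i k_j / d_ij²`, and eigenvector-weighted gravity
`WG(i) = e_i · CG(i)`.

Ground truth: discrete-time SI dynamics — every infectious node infects
each susceptible neighbor independently with probability β per step — and a
node's spreading capacity is the mean number of infected nodes after a
fixed horizon when it is the seed. Rank agreement uses Kendall's tau
(tau-b by default; tau-a and an n(n−1)-denominator variant are available).

## Worked example

```sh
spreadrank generate --model ba --n 60 --m-attach 2 --seed 3 --output toy.edges
spreadrank rank --input toy.edges --method dematel-gravity,gravity,dc --top 5 --output scores.tsv
```

prints the top-5 table and pairwise overlaps,

```
     dematel-gravity gravity  dc
rank
1                  2       2   2
2                  0       0   0
3                  3       3  14
```

and `scores.tsv` starts

```
node	method	score	rank
2	dematel-gravity	2.625392905	1
0	dematel-gravity	1.520202741	2
3	dematel-gravity	1.288457685	3
```

— node 2's importance 2.63 is its total exerted-plus-received influence
(a = R + C); the hub nodes of the preferential-attachment graph top every
method. Evaluating against SI ground truth,

```sh
spreadrank evaluate --input toy.edges --methods gravity,dematel-gravity \
    --beta-grid 0.1:0.4:0.1 --steps 8 --runs 50 --seed 1 --output tau.tsv
```

```
method	beta	tau
gravity	0.1	0.7112122341
dematel-gravity	0.1	0.7425015337
gravity	0.2	0.7070485428
dematel-gravity	0.2	0.7326735312
```

— at each infection probability, the tau-b between the DEMATEL-gravity
ranking and the simulated spreading capacities (here ≈ 0.74 at β = 0.1)
edges out plain gravity, i.e. the ranking with indirect influence tracks
the epidemic ground truth slightly better on this graph. The same
functions are available as a library (`spreadrank.rank_dematel`,
`spreadrank.correlation_experiment`, ...).

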