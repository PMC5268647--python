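# Methods

This note documents the models, conventions and numerical choices behind
`econet`, in the order a user meets them: the quality function, the graph
metrics it is built from, the filters, the community detection and
distances, the synthetic models and cohorts, and finally the simulation
protocols with the problem sizes this package runs them at.

## The quality function J

For a binary network on n nodes with m links and connection density
ρ = m / m_max (m_max = n(n−1)/2 undirected, n(n−1) directed),

    J = (Eg + El) / ρ .

All three ingredients lie in [0, 1], so J measures efficiency per unit of
wiring cost.  Its boundary behaviour anchors the tests:

* ρ → 1: Eg = El = 1 on the complete graph, so J = 2 exactly.
* Sparse, triangle-free: El = 0 and every link is a shortest path of
  length one; on a perfect matching Eg = ρ = 1/(n−1) so J = 1 exactly.
  At ρ = 0 both efficiencies vanish and J is an indefinite form — the
  package raises rather than reporting 0.

A parametrized variant 2[αEg + (1−α)El]/ρ (α ∈ [0, 1]) is provided;
α = 0.5 reproduces J identically, and on the generated topologies the
argmax density is insensitive to α except at the extremes (α → 1 on
lattices suppresses the clustering term entirely).

### Asymptotic optima

For a 1-D ring lattice of even degree k the local efficiency tends to
El∞(k) = 3(k−2)/(4(k−1)) for large n while Eg/ρ stays bounded, so
J ≈ (n−1)·El∞(k)/k.  Maximizing over continuous k gives k² − 4k + 2 = 0,
k* = 2 + √2 ≈ 3.414.  For Erdős–Rényi graphs the clustering vanishes and
Eg scales as ln k / ln n, so J ≈ (n−1)·ln k/(k ln n) with maximizer
k* = e ≈ 2.718.  `lattice_optimal_degree` / `random_graph_optimal_degree`
obtain both by bounded scalar minimization (scipy, xatol 1e−10) rather
than by quoting the closed forms, so the test against 3.414/2.718 is a
genuine cross-check of the asymptotic expressions.

Because realistic networks interpolate between regular and random order,
the optimal density is taken as ρ* = 3/(n−1) — mean degree 3,
m = round(3n/2) links — which is what `eco_filter` applies.

## Graph metrics

* **Global efficiency** — mean of 1/d(i,j) over ordered node pairs;
  unreachable pairs contribute zero (harmonic handling), which keeps the
  quantity defined on the fragmented networks sparse filtering can
  produce.  Shortest paths come from `scipy.sparse.csgraph` on the
  adjacency matrix.
* **Local efficiency** — for each node, the global efficiency of the
  subgraph induced by its neighbours (the node itself excluded); nodes
  with fewer than two neighbours contribute zero; average over all n
  nodes.  Neighbourhoods below 16 nodes use a pure-Python BFS (cheaper
  than a csgraph call at that size); larger ones go through csgraph.
  Both paths are exercised against the networkx implementation in tests.
* **Directed conventions** — density and efficiency normalize by ordered
  pairs n(n−1); the neighbourhood of a node is the union of its in- and
  out-neighbours with arc directions kept inside the induced subgraph;
  degree is total (in + out); the largest component uses weak
  connectivity.  These choices keep every quantity defined on the
  directed connectomes (Granger causality, partial directed coherence)
  without changing any undirected value.
* **Betweenness** — raw (unnormalized) shortest-path counts with
  endpoints excluded, over unordered pairs for undirected graphs
  (networkx's convention).  The divergent coefficient used downstream is
  invariant to any common scale factor, so the ordered/unordered factor
  of two is immaterial.

## Filters

All filters consume one deterministic link ranking: descending weight
(or |weight| in `absolute` mode, for signed estimators such as wavelet
correlation), ties broken by ascending index pair.  The ranking covers
every candidate pair — zero weights rank last — so density 1 reproduces
the complete graph.

* `threshold_by_density(w, ρ)` keeps the top round(ρ·m_max) links.
  Rounding is half-away-from-zero, which matters because 3n/2 is
  fractional for odd n (n = 61 keeps 92 links).
* `eco_filter` = density threshold at ρ = 3/(n−1) (round(3n) arcs when
  directed), capped at the complete graph for n ≤ 4; it warns when the
  matrix has fewer nonzero weights than the target (the criterion
  presumes m ≥ 3n/2 candidate links).
* `mst_filter` — maximum-weight spanning tree (Kruskal over the ranking,
  so tie handling is inherited); a forest when the nonzero-weight support
  is disconnected.  Trees have no triangles: El = 0 identically, and mean
  degree ≤ 2.
* `pmfg_filter` — greedy strongest-first insertion, keeping a link iff
  the graph stays planar (networkx certification); reaches the maximal
  planar bound 3(n−2) on complete weight matrices and always contains the
  spanning tree of the same ranking.
* `mst_eco_filter` — the spanning backbone topped up with the remaining
  strongest links to the ECO count round(3n/2): connected like the MST,
  dense enough to carry clustering.

## Community structure and distances

Modularity Q compares within-community adjacency against the
degree-preserving null model k_i k_j / 2m (directed inputs are
symmetrized first).  `spectral_partition` maximizes Q by recursive
bisection along the leading eigenvector of the generalized modularity
matrix, with a Kernighan–Lin-style single-node refinement after each
bisection (on by default); a split is accepted only if it increases Q,
and connected components are pre-split because the spectral problem is
degenerate across components.  Determinism: the eigenvector sign is fixed
so its largest-magnitude entry is positive, zero entries join the
positive side, and greedy ties resolve to the lowest node index.  On all
tested small graphs the result reaches at least 90% of the
exhaustive-search optimum; like any spectral heuristic it carries no
global guarantee.

Two normalized distances compare samples:

* **Mirkin index** between partitions: 2(n01 + n10)/(n(n−1)), the
  pair-counting disagreement normalized to reach exactly 1 for
  all-singletons vs all-in-one.  (The unnormalized pair count is
  divided by the number of ordered pairs; this is the constant that makes
  the stated [0, 1] range exact.)  It is the Hamming distance between
  pair-coincidence indicators, hence a metric.
* **Divergent coefficient** between nonnegative feature vectors:
  sqrt(mean(((x_u − x_v)/(x_u + x_v))²)) — Clark's divergence.  The
  square root is taken (the quantity is described as an L2-type
  distance); 0/0 coordinates contribute zero.  M = 1 for the scalar
  quantities (Eg, El, Q), M = n for degree and betweenness vectors.

Between-group tables pair every sample of one group with every sample of
the other.

## Synthetic models

* **Ring lattice** (even k): circulant graph, k/2 neighbours per side.
  **Odd mean degree** is obtained from the (k+1)-lattice by removing, for
  every odd-indexed node, the link to its left farthest neighbour
  (circular offset −(k+1)/2): exactly n/2 links go, mean degree is
  exactly k, and the structure stays regular (two degree values).  When
  the base saturates at the complete graph a perfect matching is removed
  instead, preserving the n/2 count.
* **Erdős–Rényi**: G(n, m) with m = round(ρ·m_max) — the experiments
  condition on exact density, so the fixed-m variant is used throughout.
* **Watts–Strogatz**: the (odd- or even-degree) lattice with every link
  independently rewired with probability p_ws (default 0.1), avoiding
  self-loops and duplicates; link count preserved.  p_ws = 0 returns the
  lattice exactly; p_ws = 1 is the degree-sum-preserving randomization
  used as the "random" cohort contrast.
* **Barabási–Albert**: preferential attachment with m_ba links per new
  node from a complete seed of n₀ = m_ba nodes (pre-pruning link count
  m₀ + m_ba(n − n₀), i.e. mean degree 6 − 12/n at m_ba = 3); where a
  lower degree or density is required, links are removed uniformly at
  random, which preserves the heavy degree tail.
* **Planted connectomes**: a binary topology embedded in a full weighted
  matrix — link weights uniform in [signal_low, 1], non-links uniform in
  (0, noise_high].  Defaults 0.5/0.3 separate the supports, so density
  thresholding at the planted density recovers the topology exactly;
  raising noise_high past signal_low degrades recovery smoothly.  This
  emulates the *output* of connectivity inference (a dense matrix with
  signal concentrated in the strong weights); it does not model the
  estimator-specific error structure of real modalities — spatially
  correlated noise, volume conduction, indirect (third-party) links — so
  cohort results here demonstrate the mechanics and ordering of the
  filters, not clinical effect sizes.
* **Cohorts**: two labeled groups sharing n; the default contrast is
  small-world (p_ws = 0.1) versus degree-matched randomized (p_ws = 1)
  topologies, a controlled stand-in for the healthy/diseased contrasts of
  imaging studies.  Everything is driven by numpy Generators seeded from
  a single spec seed, bit-for-bit reproducible.

## Simulation protocols and problem sizes

**Two-step density search.**  Step 1 evaluates J on 100 quadratically
spaced densities ρ_i = ρ_max·(i/100)² — quadratic spacing concentrates
resolution near zero, where the optimum lies; ρ_max is 1 except for the
pruned BA model, whose admissible interval is bounded by the grown
density.  Step 2 refines with 100 linearly spaced values between the
step-1 neighbours of the argmax.  Grids are deduplicated to distinct link
counts (with a warning when n is too small to support 100 distinct
densities).  Two implementation points:

* *Exact pruning.*  Since Eg + El ≤ 2, no graph at density ρ can score
  above 2/ρ; scanning the grid in ascending order, all candidates with
  2/ρ below the best J already found are skipped.  This leaves the argmax
  unchanged and avoids evaluating the dense half of the grid, where the
  all-pairs computations are most expensive.
* *Nested pruning.*  Each replicate draws one sample network (per base
  degree, for lattice-derived families) and removes its excess links in a
  nested fashion along the density grid, so the replicate's J values form
  a single monotone pruning profile.  Evaluating an independent
  realization per grid point instead makes the argmax noise-dominated at
  low density, where 1/ρ amplifies the variance, and biases the optimum
  downward.

**Scaling experiment.**  Sizes n ∈ {8, 16, 32, 64, 128, 256, 512}, 20
replicates per (family, size) — the sizes cover the span of typical
inferred connectomes while keeping the run on one CPU in minutes, and 20
replicates is the choice this package standardizes on for the per-size
means.  The power law ρ = c/(n−1) is fitted by least squares in the
linear model ρ = c·x with x = 1/(n−1) (closed form c = Σρx/Σx²), by
default on per-size replicate means; adjusted R² uses one model
parameter.  Note the x² weighting makes the smallest sizes dominate the
fit, so the fitted c sits below the large-n plateau of ρ(n−1) for
families whose small-n optima are lower.

**Optimal integer degree.**  At n = 4096, J is evaluated at integer mean
degrees k = 1..6 over seeded realizations: Watts–Strogatz built directly
at each k (odd k via the odd-degree lattice before rewiring), BA grown
once per seed (m_ba = 3) and pruned to each target count — targets at or
above the grown mean degree 6 − 12/n use the unpruned network.  The
argmax reported is the per-seed mode.  n = 4096 is large enough for the
asymptotic ordering J(3) > J(4) > J(2) to be stable while keeping each
evaluation at ~20 s.

**Cohort benchmark.**  Conditions are density thresholds k = 1..12
(ρ = k/(n−1)) plus the ECO/MST/PMFG/MST+ECO methods.  Per condition and
sample: Eg, El, Q, the partition itself, degree and betweenness vectors,
largest-component fraction.  Cross-group distances per quantity;
Kruskal–Wallis omnibus across conditions at α = 0.01; Tukey–Kramer
all-pairs post-hoc on rank-transformed distances at α = 0.05
(statsmodels); per-threshold two-sample rank-sum tests on the
largest-component fraction.  A degenerate case is handled explicitly:
when every distance is identical (MST local-efficiency distances are all
exactly 0) the omnibus records p = 1 instead of erroring.

## Numerical conventions and degenerate inputs

* Link counts from densities always use round-half-away-from-zero.
* J at ρ = 0 raises (indefinite form), as do metrics undefined below
  n = 2; modularity requires m ≥ 1.
* Undirected connectomes must be symmetric within 1e−9; diagonals are
  zeroed (file readers warn when they were not); non-finite weights are
  rejected at ranking time.
* Exactly tied weights at a density cut are resolved by the index-pair
  tie rule — a repository convention, stated once and used everywhere.
* Eg is non-decreasing along link addition and is asserted as such; El
  is *not* monotone per instance (a pendant link added to a triangle
  lowers it), although it grows along typical density sweeps — the
  profile object therefore validates monotone ρ and Eg only.

## Known limitations

* The spectral partitioner is a deterministic heuristic; its Q can trail
  the true optimum on adversarial small graphs (the suite bounds the gap
  at 10% for n ≤ 8).
* ECO does not guarantee connectedness; fragmented output is expected at
  k ≃ 3 on random-like topologies (the largest component typically keeps
  well over half the nodes, and the MST+ECO hybrid exists precisely for
  users who need a connected backbone).
* The planted-weight scheme is exchangeable across pairs; nothing in the
  package models estimator-specific artifacts (indirect links, spatial
  leakage), so benchmark effect sizes do not translate to real
  modalities.
* The weighted-network extension of the criterion (optimizing weighted
  efficiencies directly) is out of scope.
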