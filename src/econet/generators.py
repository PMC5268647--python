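"""Synthetic network models and weighted-connectome fixtures.

Four binary-topology families:

* ring lattices (even degree; an odd-degree variant removes one link per
  odd node, keeping the structure regular),
* Erdos-Renyi G(n, m) random graphs with an exact link count,
* Watts-Strogatz small-world graphs (lattice plus independent link
  rewiring),
* Barabasi-Albert scale-free graphs grown from a complete seed and pruned
  at random down to a target link budget, which preserves the heavy tail.

Weighted fixtures plant a binary topology inside a full matrix by drawing
link weights from [signal_low, 1] and non-link weights from
(0, noise_high]; when the two supports are separated, density thresholding
at the planted density recovers the topology exactly.  Everything is
seeded and reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from typing import Callable, Optional

import networkx as nx
import numpy as np

from ._util import as_rng, pair_count, round_half_away, spawn_seed
from .cohort import CohortSpec, CohortStudy, ModelSpec
from .filtering import WeightedConnectome
from .graph import BinaryGraph

__all__ = [
    "ring_lattice",
    "odd_k_lattice",
    "er_random",
    "watts_strogatz",
    "ba_network",
    "directed_variant",
    "planted_connectome",
    "two_group_cohort",
    "generate_model",
    "remove_random_links",
    "density_sampler",
    "DensitySampler",
]


# ---------------------------------------------------------------------------
# binary topologies
# ---------------------------------------------------------------------------


def ring_lattice(n: int, k: int) -> BinaryGraph:
    """Circulant graph: each node linked to its k/2 nearest neighbours per side."""
    if k % 2:
        raise ValueError("ring_lattice requires even k; use odd_k_lattice")
    if not 0 <= k < n:
        raise ValueError("ring_lattice requires 0 <= k < n")
    links = []
    for off in range(1, k // 2 + 1):
        for i in range(n):
            links.append((i, (i + off) % n))
    return BinaryGraph(n, links)


def odd_k_lattice(n: int, k: int) -> BinaryGraph:
    """Regular-ish lattice with odd mean degree k (n must be even).

    Built from the even lattice of degree k+1 by removing, for every
    odd-indexed node, the link to its left farthest neighbour (circular
    offset -(k+1)/2).  Exactly n/2 links are removed, so the mean degree
    is exactly k while the structure stays regular.
    """
    if n % 2:
        raise ValueError("odd_k_lattice requires even n")
    if k % 2 == 0:
        raise ValueError("odd_k_lattice requires odd k; use ring_lattice")
    if not 1 <= k < n:
        raise ValueError("odd_k_lattice requires 1 <= k < n")
    if k + 1 >= n:
        # The even-degree base saturates at the complete graph; removing a
        # perfect matching still deletes exactly n/2 links.
        base = {(i, j) for i in range(n) for j in range(i + 1, n)}
        for i in range(n // 2):
            base.discard((i, i + n // 2))
        return BinaryGraph(n, base)
    base = ring_lattice(n, k + 1)
    off = (k + 1) // 2
    links = set(base.links)
    removed = 0
    for i in range(1, n, 2):
        j = (i - off) % n
        pair = (i, j) if i < j else (j, i)
        if pair not in links:
            raise RuntimeError("odd-k construction invariant violated")
        links.remove(pair)
        removed += 1
    assert removed == n // 2
    return BinaryGraph(n, links)


def er_random(
    n: int, rho: float, directed: bool = False, seed=None
) -> BinaryGraph:
    """G(n, m) random graph with exactly m = round(rho * max_links) links."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = as_rng(seed)
    m = round_half_away(rho * pair_count(n, directed))
    G = nx.gnm_random_graph(n, m, seed=spawn_seed(rng), directed=directed)
    return BinaryGraph(n, G.edges(), directed=directed)


def watts_strogatz(n: int, k: int, p_ws: float = 0.1, seed=None) -> BinaryGraph:
    """Small-world graph: (odd- or even-degree) lattice plus link rewiring.

    Every lattice link is independently rewired with probability ``p_ws``:
    the link (u, v) is replaced by (u, w) with w drawn uniformly, avoiding
    self-loops and duplicates.  The link count is preserved.
    """
    if not 0.0 <= p_ws <= 1.0:
        raise ValueError("rewiring probability must lie in [0, 1]")
    rng = as_rng(seed)
    base = ring_lattice(n, k) if k % 2 == 0 else odd_k_lattice(n, k)
    links = set(base.links)
    nbrs = [set() for _ in range(n)]
    for u, v in links:
        nbrs[u].add(v)
        nbrs[v].add(u)
    for u, v in sorted(base.links):
        if rng.random() >= p_ws:
            continue
        if len(nbrs[u]) >= n - 1:
            continue  # u saturated; nowhere to rewire
        while True:
            w = int(rng.integers(n))
            if w != u and w not in nbrs[u]:
                break
        links.remove((u, v) if u < v else (v, u))
        nbrs[u].discard(v)
        nbrs[v].discard(u)
        links.add((u, w) if u < w else (w, u))
        nbrs[u].add(w)
        nbrs[w].add(u)
    return BinaryGraph(n, links)


def _ba_tree(n: int, rng: np.random.Generator) -> BinaryGraph:
    """Preferential-attachment tree (the m_ba = 1 case, grown by hand)."""
    links = [(0, 1)]
    repeated = [0, 1]
    for new in range(2, n):
        target = repeated[int(rng.integers(len(repeated)))]
        links.append((target, new))
        repeated.extend((target, new))
    return BinaryGraph(n, links)


def ba_network(
    n: int,
    m_ba: int = 3,
    target_k: Optional[float] = None,
    target_rho: Optional[float] = None,
    seed=None,
) -> BinaryGraph:
    """Barabasi-Albert graph from a complete n0 = m_ba seed, then pruned.

    Growth attaches each new node with ``m_ba`` preferential links, so the
    pre-pruning link count is m0 + m_ba (n - n0) with m0 = n0(n0-1)/2.
    If a target mean degree or density is given, links are then removed
    uniformly at random down to that count, which preserves the scale-free
    degree tail.
    """
    if target_k is not None and target_rho is not None:
        raise ValueError("give at most one of target_k and target_rho")
    if not 1 <= m_ba < n:
        raise ValueError("ba_network requires 1 <= m_ba < n")
    rng = as_rng(seed)
    if m_ba == 1:
        g = _ba_tree(n, rng)
    else:
        G = nx.barabasi_albert_graph(
            n, m_ba, seed=spawn_seed(rng), initial_graph=nx.complete_graph(m_ba)
        )
        g = BinaryGraph(n, G.edges())
    if target_k is None and target_rho is None:
        return g
    if target_k is not None:
        m_t = round_half_away(target_k * n / 2)
    else:
        m_t = round_half_away(target_rho * pair_count(n, False))
    if m_t > g.m:
        raise ValueError(
            f"target link count {m_t} exceeds the {g.m} links grown "
            f"(m_ba={m_ba}, n={n})"
        )
    return remove_random_links(g, g.m - m_t, rng)


def remove_random_links(g: BinaryGraph, count: int, seed=None) -> BinaryGraph:
    """Delete ``count`` links chosen uniformly at random (seeded)."""
    if count < 0 or count > g.m:
        raise ValueError("cannot remove more links than exist")
    if count == 0:
        return g
    rng = as_rng(seed)
    links = g.sorted_links()
    keep_idx = rng.choice(len(links), size=len(links) - count, replace=False)
    return BinaryGraph(g.n, [links[i] for i in sorted(keep_idx)], directed=g.directed)


def directed_variant(
    g: BinaryGraph, seed=None, p_bidirectional: float = 0.0
) -> BinaryGraph:
    """Assign random orientations to the links of an undirected graph.

    Each link becomes both arcs with probability ``p_bidirectional``,
    otherwise a single arc with a uniformly random orientation.
    """
    if g.directed:
        raise ValueError("directed_variant expects an undirected input")
    rng = as_rng(seed)
    arcs = []
    for u, v in g.sorted_links():
        if p_bidirectional > 0 and rng.random() < p_bidirectional:
            arcs.extend(((u, v), (v, u)))
        elif rng.random() < 0.5:
            arcs.append((u, v))
        else:
            arcs.append((v, u))
    return BinaryGraph(g.n, arcs, directed=True)


# ---------------------------------------------------------------------------
# weighted fixtures
# ---------------------------------------------------------------------------


def planted_connectome(
    g: BinaryGraph,
    signal_low: float = 0.5,
    noise_high: float = 0.3,
    seed=None,
) -> WeightedConnectome:
    """Embed a binary topology in a full weighted matrix.

    Links of ``g`` get weights uniform in [signal_low, 1]; every other
    candidate pair gets "noise" uniform in (0, noise_high].  When
    signal_low > noise_high, thresholding at the planted density recovers
    ``g`` exactly.
    """
    if not (0 < noise_high <= 1 and 0 < signal_low <= 1):
        raise ValueError("signal_low and noise_high must lie in (0, 1]")
    rng = as_rng(seed)
    n = g.n
    w = np.zeros((n, n))
    if g.directed:
        ii, jj = np.nonzero(~np.eye(n, dtype=bool))
    else:
        ii, jj = np.triu_indices(n, 1)
    noise = noise_high * (1.0 - rng.random(len(ii)))  # in (0, noise_high]
    w[ii, jj] = noise
    for u, v in g.sorted_links():
        w[u, v] = signal_low + (1.0 - signal_low) * rng.random()
    if not g.directed:
        w = np.triu(w, 1)
        w = w + w.T
    return WeightedConnectome(w, directed=g.directed)


def generate_model(spec: ModelSpec, seed=None) -> BinaryGraph:
    """Instantiate a binary topology from a ModelSpec."""
    rng = as_rng(spec.seed if seed is None else seed)
    n = spec.n
    if spec.family == "er":
        rho = spec.rho if spec.rho is not None else spec.k / (n - 1)
        g = er_random(n, rho, seed=rng)
    elif spec.family == "lattice":
        k = spec.k if spec.k is not None else spec.rho * (n - 1)
        k = int(round(k))
        g = ring_lattice(n, k) if k % 2 == 0 else odd_k_lattice(n, k)
    elif spec.family == "ws":
        k = spec.k if spec.k is not None else spec.rho * (n - 1)
        g = watts_strogatz(n, int(round(k)), spec.p_ws, seed=rng)
    else:  # ba
        g = ba_network(n, spec.m_ba, target_k=spec.k, target_rho=spec.rho, seed=rng)
    if spec.directed:
        g = directed_variant(g, seed=rng)
    return g


def two_group_cohort(spec: CohortSpec) -> CohortStudy:
    """Generate the two labeled groups of weighted connectomes of a spec."""
    rng = as_rng(spec.seed)
    groups = {}
    for label, model in zip(spec.labels, (spec.group_a, spec.group_b)):
        samples = []
        for _ in range(spec.samples_per_group):
            g = generate_model(model, seed=rng)
            samples.append(
                planted_connectome(g, spec.signal_low, spec.noise_high, seed=rng)
            )
        groups[label] = samples
    return CohortStudy(groups=groups, spec=spec)


# ---------------------------------------------------------------------------
# density-parametrized samplers for the optimal-density search
# ---------------------------------------------------------------------------


class DensitySampler:
    """Model family exposed as ``sampler(n, rho, rng) -> BinaryGraph``.

    At a requested density the sampler produces a graph with exactly
    m = round(rho * max_links) links, following the simulation protocol:

    * ``lattice``: even lattice of degree nearest-even >= rho(n-1), excess
      links removed at random;
    * ``er``: G(n, m);
    * ``ws``: the lattice, rewired with probability ``p_ws``, then pruned;
    * ``ba``: growth with m_ba = round(log2 n) attachment links from a
      complete seed, pruned at random — the admissible density interval is
      therefore bounded above by the grown density (see ``rho_max``).

    ``for_replicate`` returns the sampler the density search uses: one
    sample network per replicate whose excess links are removed at random
    in a *nested* fashion, so the graphs evaluated along the density grid
    form a single monotone pruning of that replicate's network (fresh
    independent realizations per grid point would make the argmax of J
    noise-dominated at low density, where 1/rho amplifies the variance).
    """

    def __init__(self, family: str, p_ws: float = 0.1):
        if family not in ("lattice", "er", "ws", "ba"):
            raise ValueError(f"unknown sampler family {family!r}")
        self.family = family
        self.p_ws = p_ws
        self.directed = False

    def _m_ba(self, n: int) -> int:
        return max(2, int(round(math.log2(n))))

    def rho_max(self, n: int) -> float:
        if self.family != "ba":
            return 1.0
        m_ba = self._m_ba(n)
        grown = m_ba * (m_ba - 1) // 2 + m_ba * (n - m_ba)
        return grown / pair_count(n, False)

    def _lattice_base(self, n: int, m: int) -> BinaryGraph:
        k = 2 * math.ceil(m * 2 / n / 2)  # nearest even >= mean degree 2m/n
        while k < n and n * k // 2 < m:
            k += 2
        if k >= n:
            return BinaryGraph(n, ((i, j) for i in range(n) for j in range(i + 1, n)))
        return ring_lattice(n, k)

    def __call__(self, n: int, rho: float, rng) -> BinaryGraph:
        rng = as_rng(rng)
        m = round_half_away(rho * pair_count(n, False))
        if self.family == "er":
            G = nx.gnm_random_graph(n, m, seed=spawn_seed(rng))
            return BinaryGraph(n, G.edges())
        if self.family == "lattice":
            base = self._lattice_base(n, m)
            return remove_random_links(base, base.m - m, rng)
        if self.family == "ws":
            base = self._lattice_base(n, m)
            k = int(round(2 * base.m / n))
            if k % 2 == 0 and k < n:  # a proper ring lattice: rewire it
                g = watts_strogatz(n, k, self.p_ws, seed=rng)
            else:  # saturated (complete) base; rewiring is a no-op
                g = base
            return remove_random_links(g, g.m - m, rng)
        # ba: grown once at full density, pruned to the requested count
        base = ba_network(n, self._m_ba(n), seed=rng)
        if m > base.m:
            m = base.m
        return remove_random_links(base, base.m - m, rng)

    def for_replicate(self, n: int, rng) -> Callable:
        """Per-replicate sampler with nested random pruning (see class doc)."""
        rng = as_rng(rng)

        if self.family == "er":
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            order = rng.permutation(len(pairs))

            def sample_er(n_: int, rho: float, rng_) -> BinaryGraph:
                m = round_half_away(rho * pair_count(n_, False))
                return BinaryGraph(n_, (pairs[t] for t in order[:m]))

            return sample_er

        if self.family == "ba":
            base = ba_network(n, self._m_ba(n), seed=rng)
            links = base.sorted_links()
            order = rng.permutation(len(links))

            def sample_ba(n_: int, rho: float, rng_) -> BinaryGraph:
                m = min(round_half_away(rho * pair_count(n_, False)), len(links))
                return BinaryGraph(n_, (links[t] for t in order[:m]))

            return sample_ba

        # lattice / ws: the base depends on the requested density through
        # its even degree; one retention order is drawn per base degree,
        # so the pruning is nested within each base.
        orders: dict = {}

        def sample_lat(n_: int, rho: float, rng_) -> BinaryGraph:
            m = round_half_away(rho * pair_count(n_, False))
            base = self._lattice_base(n_, m)
            key = base.m
            if key not in orders:
                if self.family == "ws":
                    k = int(round(2 * base.m / n_))
                    if k % 2 == 0 and k < n_:
                        base = watts_strogatz(n_, k, self.p_ws, seed=rng)
                links = base.sorted_links()
                orders[key] = [links[t] for t in rng.permutation(len(links))]
            return BinaryGraph(n_, orders[key][:m])

        return sample_lat


def density_sampler(family: str, p_ws: float = 0.1) -> DensitySampler:
    """Factory for the density-parametrized model samplers."""
    return DensitySampler(family, p_ws=p_ws)
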