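"""Binary (unweighted) graphs and the topological metrics built on them.

The container is deliberately minimal: a node count, a directedness flag
and a set of links.  All node/graph-level quantities used by the ECO
criterion live here:

* connection density rho,
* global efficiency Eg (mean inverse shortest-path length; the harmonic
  handling makes it well defined on fragmented graphs, where unreachable
  pairs simply contribute zero),
* local efficiency El (mean, over nodes, of the global efficiency of each
  node's neighbourhood subgraph),
* degree and betweenness vectors,
* largest connected component fraction.

Shortest paths are delegated to ``scipy.sparse.csgraph``; betweenness and
component bookkeeping to ``networkx``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse import csgraph

from ._util import pair_count

__all__ = [
    "BinaryGraph",
    "MetricVector",
    "density",
    "shortest_path_lengths",
    "global_efficiency",
    "local_efficiency",
    "degree_vector",
    "betweenness_vector",
    "largest_component_fraction",
]

Link = Tuple[int, int]

# Neighbourhood size above which induced-subgraph efficiencies are computed
# through scipy's C shortest-path code instead of a pure-Python BFS.
_CSGRAPH_CUTOFF = 16


class BinaryGraph:
    """An unweighted (di)graph on nodes ``0..n-1`` with no self-loops.

    Links are stored canonically: unordered ``(min, max)`` pairs when
    undirected, ordered ``(source, target)`` pairs when directed.
    Instances are immutable in intent; adjacency structures are cached
    lazily.
    """

    __slots__ = ("n", "directed", "links", "_adj", "_out_nbrs", "_all_nbrs")

    def __init__(self, n: int, links: Iterable[Link] = (), directed: bool = False):
        n = int(n)
        if n < 1:
            raise ValueError("a graph needs at least one node")
        directed = bool(directed)
        canon = set()
        for u, v in links:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop on node {u} is not allowed")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"link ({u}, {v}) outside node range [0, {n})")
            if not directed and u > v:
                u, v = v, u
            canon.add((u, v))
        self.n = n
        self.directed = directed
        self.links = frozenset(canon)
        self._adj = None
        self._out_nbrs = None
        self._all_nbrs = None

    # -- basic accessors ---------------------------------------------------

    @property
    def m(self) -> int:
        """Number of links (arcs if directed)."""
        return len(self.links)

    @property
    def max_links(self) -> int:
        return pair_count(self.n, self.directed)

    def has_link(self, u: int, v: int) -> bool:
        if not self.directed and u > v:
            u, v = v, u
        return (u, v) in self.links

    def sorted_links(self) -> list:
        return sorted(self.links)

    def adjacency(self) -> csr_matrix:
        """Sparse adjacency matrix (symmetric when undirected)."""
        if self._adj is None:
            if self.links:
                arr = np.array(sorted(self.links), dtype=np.intp)
                rows, cols = arr[:, 0], arr[:, 1]
                if not self.directed:
                    rows, cols = np.concatenate([rows, cols]), np.concatenate([cols, rows])
            else:
                rows = cols = np.empty(0, dtype=np.intp)
            data = np.ones(len(rows), dtype=np.float64)
            self._adj = csr_matrix((data, (rows, cols)), shape=(self.n, self.n))
        return self._adj

    def out_neighbors(self) -> list:
        """Per-node list of out-neighbours (all neighbours if undirected)."""
        if self._out_nbrs is None:
            nbrs = [[] for _ in range(self.n)]
            for u, v in self.links:
                nbrs[u].append(v)
                if not self.directed:
                    nbrs[v].append(u)
            self._out_nbrs = nbrs
        return self._out_nbrs

    def all_neighbors(self) -> list:
        """Per-node list of neighbours, union of in- and out- when directed."""
        if self._all_nbrs is None:
            if not self.directed:
                self._all_nbrs = self.out_neighbors()
            else:
                nbrs = [set() for _ in range(self.n)]
                for u, v in self.links:
                    nbrs[u].add(v)
                    nbrs[v].add(u)
                self._all_nbrs = [sorted(s) for s in nbrs]
        return self._all_nbrs

    def as_undirected(self) -> "BinaryGraph":
        """Symmetrized copy (identity if already undirected)."""
        if not self.directed:
            return self
        return BinaryGraph(self.n, self.links, directed=False)

    # -- conversions -------------------------------------------------------

    def to_networkx(self):
        G = nx.DiGraph() if self.directed else nx.Graph()
        G.add_nodes_from(range(self.n))
        G.add_edges_from(sorted(self.links))
        return G

    @classmethod
    def from_networkx(cls, G) -> "BinaryGraph":
        nodes = sorted(G.nodes())
        index = {u: i for i, u in enumerate(nodes)}
        links = [(index[u], index[v]) for u, v in G.edges()]
        return cls(len(nodes), links, directed=G.is_directed())

    # -- dunder ------------------------------------------------------------

    def __eq__(self, other):
        if not isinstance(other, BinaryGraph):
            return NotImplemented
        return (self.n, self.directed, self.links) == (other.n, other.directed, other.links)

    def __hash__(self):
        return hash((self.n, self.directed, self.links))

    def __repr__(self):
        kind = "directed" if self.directed else "undirected"
        return f"BinaryGraph(n={self.n}, m={self.m}, {kind})"


@dataclass(frozen=True)
class MetricVector:
    """A per-node metric (degree, betweenness, ...) with its name."""

    values: np.ndarray
    metric_name: str

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    def __len__(self):
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def __getitem__(self, i):
        return self.values[i]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def density(g: BinaryGraph) -> float:
    """Connection density: realized links over candidate node pairs."""
    if g.n < 2:
        raise ValueError("density is undefined for graphs with fewer than 2 nodes")
    return g.m / g.max_links


def shortest_path_lengths(g: BinaryGraph) -> np.ndarray:
    """All-pairs unweighted shortest-path matrix; ``inf`` marks unreachable."""
    if g.m == 0:
        d = np.full((g.n, g.n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return csgraph.shortest_path(
        g.adjacency(), method="D", unweighted=True, directed=g.directed
    )


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Unreachable pairs contribute zero, so the quantity stays defined on
    fragmented graphs.  Equals 1 exactly on complete graphs.
    """
    if g.n < 2:
        raise ValueError("global efficiency is undefined for graphs with fewer than 2 nodes")
    if g.m == 0:
        return 0.0
    d = shortest_path_lengths(g)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0  # diagonal (1/0) and unreachable (1/inf)
    return float(inv.sum()) / (g.n * (g.n - 1))


def _subgraph_efficiency_bfs(nodes, out_nbrs) -> float:
    """Efficiency of an induced subgraph via per-source BFS (small d)."""
    nodeset = set(nodes)
    d = len(nodes)
    inv_sum = 0.0
    for s in nodes:
        seen = {s}
        frontier = [s]
        depth = 0
        while frontier:
            depth += 1
            inv_d = 1.0 / depth
            nxt = []
            for u in frontier:
                for v in out_nbrs[u]:
                    if v in nodeset and v not in seen:
                        seen.add(v)
                        nxt.append(v)
                        inv_sum += inv_d
            frontier = nxt
    return inv_sum / (d * (d - 1))


def _subgraph_efficiency_csgraph(adj, nodes, directed) -> float:
    idx = np.asarray(nodes, dtype=np.intp)
    sub = adj[idx][:, idx]
    d = csgraph.shortest_path(sub, method="D", unweighted=True, directed=directed)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    k = len(nodes)
    return float(inv.sum()) / (k * (k - 1))


def local_efficiency(g: BinaryGraph) -> float:
    """Average over nodes of the efficiency of the neighbourhood subgraph.

    The subgraph induced by node i's neighbours excludes i itself; nodes
    with fewer than two neighbours contribute zero.  For directed graphs
    the neighbourhood is the union of in- and out-neighbours and the
    induced subgraph keeps arc directions.
    """
    if g.n < 1:
        raise ValueError("graph has no nodes")
    all_nbrs = g.all_neighbors()
    out_nbrs = g.out_neighbors()
    adj = None
    total = 0.0
    for i in range(g.n):
        nb = all_nbrs[i]
        if len(nb) < 2:
            continue
        if len(nb) >= _CSGRAPH_CUTOFF:
            if adj is None:
                adj = g.adjacency()
            total += _subgraph_efficiency_csgraph(adj, nb, g.directed)
        else:
            total += _subgraph_efficiency_bfs(nb, out_nbrs)
    return total / g.n


def degree_vector(g: BinaryGraph) -> MetricVector:
    """Node degrees; total (in + out) degree for directed graphs."""
    deg = np.zeros(g.n, dtype=np.float64)
    for u, v in g.links:
        deg[u] += 1
        deg[v] += 1
    return MetricVector(deg, "degree")


def betweenness_vector(g: BinaryGraph) -> MetricVector:
    """Unnormalized shortest-path betweenness, endpoints excluded.

    Counts over unordered source-target pairs for undirected graphs and
    over ordered pairs for directed ones.
    """
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    return MetricVector(np.array([bc[i] for i in range(g.n)]), "betweenness")


def largest_component_fraction(g: BinaryGraph) -> float:
    """Size of the largest (weakly) connected component over n."""
    G = g.to_networkx()
    comps = nx.weakly_connected_components(G) if g.directed else nx.connected_components(G)
    return max(len(c) for c in comps) / g.n
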