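"""Turning dense weighted connectivity matrices into sparse binary graphs.

A connectivity-inference step (correlation, coherence, Granger causality,
tractography counts, ...) yields a full weighted matrix W.  The filters
here retain a subset of the strongest links and binarize them:

* ``threshold_by_density`` — keep the top fraction rho of candidate links;
* ``eco_filter`` — density thresholding at rho = 3/(n-1), i.e. mean degree
  about 3, the efficiency/cost optimum;
* ``mst_filter`` — the maximum-weight spanning tree/forest (the acyclic
  strongest backbone, often called "the MST filter" in connectomics);
* ``pmfg_filter`` — greedy strongest-first insertion constrained to
  planarity (planar maximally filtered graph);
* ``mst_eco_filter`` — the spanning backbone topped up with the remaining
  strongest links until the ECO link count is reached.

All filters consume a deterministic ``LinkRanking`` (descending weight,
ties broken by ascending index pair) so the results are reproducible
bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from ._util import pair_count, round_half_away
from .graph import BinaryGraph

__all__ = [
    "WeightedConnectome",
    "LinkRanking",
    "rank_links",
    "threshold_by_density",
    "threshold_by_weight",
    "eco_filter",
    "mst_filter",
    "pmfg_filter",
    "mst_eco_filter",
]

_SYM_TOL = 1e-9


class WeightedConnectome:
    """A dense real-valued connectivity matrix with a directedness flag.

    The diagonal is ignored (zeroed on construction).  Undirected
    connectomes must be symmetric within 1e-9.
    """

    __slots__ = ("weights", "directed", "node_labels")

    def __init__(
        self,
        weights,
        directed: bool = False,
        node_labels: Optional[Sequence[str]] = None,
    ):
        w = np.array(weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome weights must form a square matrix")
        if w.shape[0] < 2:
            raise ValueError("a connectome needs at least two nodes")
        if not directed:
            finite = np.isfinite(w)
            both = finite & finite.T
            if np.any(np.abs(np.where(both, w - w.T, 0.0)) > _SYM_TOL):
                raise ValueError(
                    "matrix declared undirected but asymmetric beyond 1e-9"
                )
        np.fill_diagonal(w, 0.0)
        w.setflags(write=False)
        self.weights = w
        self.directed = bool(directed)
        if node_labels is not None:
            node_labels = tuple(str(x) for x in node_labels)
            if len(node_labels) != w.shape[0]:
                raise ValueError("node_labels length does not match matrix size")
        self.node_labels = node_labels

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def max_links(self) -> int:
        return pair_count(self.n, self.directed)

    def nonzero_link_count(self) -> int:
        if self.directed:
            off = ~np.eye(self.n, dtype=bool)
            return int(np.count_nonzero(self.weights[off]))
        iu = np.triu_indices(self.n, 1)
        return int(np.count_nonzero(self.weights[iu]))

    def __repr__(self):
        kind = "directed" if self.directed else "undirected"
        return f"WeightedConnectome(n={self.n}, {kind})"


@dataclass(frozen=True)
class LinkRanking:
    """Candidate links ordered for insertion, strongest first.

    Covers every candidate node pair (zero weights rank last), so a
    density-1 threshold reproduces the complete graph.  Order is strictly
    deterministic: descending weight (or magnitude), ties broken by
    ascending ``(i, j)``.
    """

    pairs: Tuple[Tuple[int, int], ...]
    weights: Tuple[float, ...]
    mode: str
    directed: bool
    n: int

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, key):
        return self.pairs[key]

    def top(self, m: int) -> Tuple[Tuple[int, int], ...]:
        return self.pairs[:m]


def rank_links(w: WeightedConnectome, mode: str = "raw") -> LinkRanking:
    """Order all candidate links by strength.

    ``mode='raw'`` sorts on the signed weight; ``mode='absolute'`` on its
    magnitude (for signed estimators such as wavelet correlation).
    """
    if mode not in ("raw", "absolute", "abs"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    if mode == "abs":
        mode = "absolute"
    n = w.n
    if w.directed:
        ii, jj = np.nonzero(~np.eye(n, dtype=bool))
    else:
        ii, jj = np.triu_indices(n, 1)
    vals = w.weights[ii, jj]
    if not np.all(np.isfinite(vals)):
        raise ValueError("connectome contains non-finite weights")
    key = np.abs(vals) if mode == "absolute" else vals
    order = np.lexsort((jj, ii, -key))
    pairs = tuple((int(ii[t]), int(jj[t])) for t in order)
    return LinkRanking(
        pairs=pairs,
        weights=tuple(float(vals[t]) for t in order),
        mode=mode,
        directed=w.directed,
        n=n,
    )


def threshold_by_density(
    w: WeightedConnectome, rho: float, mode: str = "raw"
) -> BinaryGraph:
    """Retain and binarize the strongest fraction ``rho`` of candidate links."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    ranking = rank_links(w, mode)
    m = round_half_away(rho * w.max_links)
    return BinaryGraph(w.n, ranking.top(m), directed=w.directed)


def threshold_by_weight(
    w: WeightedConnectome, tmin: float, mode: str = "raw"
) -> BinaryGraph:
    """Retain links whose weight (or |weight|) is at least ``tmin``.

    The weight-based counterpart of density thresholding; unlike a density
    cut it yields different link counts across samples of the same size.
    """
    ranking = rank_links(w, mode)
    key = (abs(v) for v in ranking.weights) if mode == "absolute" else ranking.weights
    links = [p for p, v in zip(ranking.pairs, key) if v >= tmin]
    return BinaryGraph(w.n, links, directed=w.directed)


def eco_filter(w: WeightedConnectome, mode: str = "raw") -> BinaryGraph:
    """Density thresholding at the efficiency/cost optimum rho = 3/(n-1).

    Keeps round(3n/2) links (round(3n) arcs when directed), capped at the
    complete graph for very small n.  Warns when the matrix carries fewer
    nonzero weights than that, in which case the trailing retained "links"
    are zero-weight pairs.
    """
    n = w.n
    if n < 3:
        raise ValueError("eco_filter requires at least 3 nodes")
    target = round_half_away(3 * n) if w.directed else round_half_away(1.5 * n)
    m = min(target, w.max_links)
    if w.nonzero_link_count() < m:
        warnings.warn(
            f"only {w.nonzero_link_count()} nonzero weights available for "
            f"{m} ECO links; zero-weight pairs will be retained",
            stacklevel=2,
        )
    ranking = rank_links(w, mode)
    return BinaryGraph(n, ranking.top(m), directed=w.directed)


def _symmetrized(w: WeightedConnectome) -> WeightedConnectome:
    if not w.directed:
        return w
    sym = np.maximum(w.weights, w.weights.T)
    return WeightedConnectome(sym, directed=False, node_labels=w.node_labels)


def _mst_links(ranking: LinkRanking, n: int) -> list:
    """Kruskal on the (descending-weight) ranking; zero weights excluded."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = []
    for (u, v), wt in zip(ranking.pairs, ranking.weights):
        if wt == 0.0:
            continue
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.append((u, v))
            if len(tree) == n - 1:
                break
    return tree


def mst_filter(w: WeightedConnectome, mode: str = "raw") -> BinaryGraph:
    """Maximum-weight spanning tree (forest on disconnected weight support).

    Directed input is symmetrized by the elementwise max of the two arc
    weights.  The output is acyclic, hence triangle-free: its local
    efficiency is exactly zero.
    """
    w = _symmetrized(w)
    ranking = rank_links(w, mode)
    return BinaryGraph(w.n, _mst_links(ranking, w.n), directed=False)


def pmfg_filter(w: WeightedConnectome, mode: str = "raw") -> BinaryGraph:
    """Planar maximally filtered graph: greedy strongest-first insertion.

    Each candidate link (nonzero weight, strongest first) is kept iff the
    graph stays planar.  On a complete weight matrix the result carries
    exactly 3(n-2) links, the maximal-planar bound, and contains the
    maximum-weight spanning tree of the same ranking.
    """
    if w.directed:
        raise ValueError("pmfg_filter requires an undirected connectome")
    if w.n < 3:
        raise ValueError("pmfg_filter requires at least 3 nodes")
    ranking = rank_links(w, mode)
    limit = 3 * (w.n - 2)
    G = nx.Graph()
    G.add_nodes_from(range(w.n))
    kept = []
    for (u, v), wt in zip(ranking.pairs, ranking.weights):
        if wt == 0.0:
            continue
        G.add_edge(u, v)
        planar, _ = nx.check_planarity(G, counterexample=False)
        if planar:
            kept.append((u, v))
            if len(kept) == limit:
                break
        else:
            G.remove_edge(u, v)
    return BinaryGraph(w.n, kept, directed=False)


def mst_eco_filter(w: WeightedConnectome, mode: str = "raw") -> BinaryGraph:
    """Spanning backbone plus strongest extra links up to the ECO count.

    Guarantees connectedness whenever the spanning tree itself spans, at
    the same average degree (k = 3) as the ECO filter.
    """
    w = _symmetrized(w)
    n = w.n
    ranking = rank_links(w, mode)
    tree = set(_mst_links(ranking, n))
    target = min(round_half_away(1.5 * n), w.max_links)
    if target < n - 1:  # impossible for n >= 3; guard anyway
        target = n - 1
    links = list(tree)
    for pair in ranking.pairs:
        if len(links) >= target:
            break
        if pair not in tree:
            links.append(pair)
    return BinaryGraph(n, links, directed=False)
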