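"""Readers and writers for connectomes, graphs, profiles and reports.

Formats: dense matrix TSV/CSV (optional header + index labels), weighted
edge-list TSV (source, target, [weight]), GraphML (via networkx),
partition TSV, profile TSV and JSON reports.  Floats are written with 12
significant digits; field order is deterministic.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .filtering import WeightedConnectome
from .graph import BinaryGraph
from .partitioning import Partition

__all__ = [
    "read_connectome",
    "read_graph",
    "write_graph",
    "write_connectome",
    "write_profile",
    "write_partition",
    "write_report",
]

_FLOAT_FMT = "%.12g"


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_dense(path: Path, directed: bool) -> WeightedConnectome:
    sep = _delimiter_for(path)
    first = path.read_text().lstrip().splitlines()[0]
    tokens = first.strip().split(sep)

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if all(_numeric(t) for t in tokens if t != ""):
        w = np.loadtxt(path, delimiter=sep, ndmin=2)
        labels = None
    else:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
        w = df.to_numpy(dtype=float)
        labels = [str(c) for c in df.columns]
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: dense connectome matrix must be square")
    if np.any(np.diag(w) != 0):
        warnings.warn(f"{path}: nonzero diagonal entries ignored (zeroed)")
    return WeightedConnectome(w, directed=directed, node_labels=labels)


def _read_edgelist_connectome(path: Path, directed: bool) -> WeightedConnectome:
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.shape[1] == 2:
        df[2] = 1.0
    if df.shape[1] != 3:
        raise ValueError(f"{path}: edge list needs 2 or 3 columns")
    df.columns = ["source", "target", "weight"]
    nodes = sorted(set(df["source"].astype(str)) | set(df["target"].astype(str)),
                   key=lambda s: (len(s), s))
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    seen = set()
    for _, row in df.iterrows():
        i, j = index[str(row["source"])], index[str(row["target"])]
        if i == j:
            raise ValueError(f"{path}: self-loop on node {row['source']!r}")
        key = (i, j) if directed else (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"{path}: duplicate link {row['source']!r}-{row['target']!r}")
        seen.add(key)
        w[i, j] = float(row["weight"])
        if not directed:
            w[j, i] = float(row["weight"])
    return WeightedConnectome(w, directed=directed, node_labels=nodes)


def _read_graphml_connectome(path: Path, directed: bool) -> WeightedConnectome:
    G = nx.read_graphml(path)
    nodes = sorted(G.nodes(), key=lambda s: (len(str(s)), str(s)))
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, data in G.edges(data=True):
        i, j = index[u], index[v]
        w[i, j] = float(data.get("weight", 1.0))
        if not G.is_directed():
            w[j, i] = w[i, j]
    return WeightedConnectome(
        w, directed=directed or G.is_directed(), node_labels=[str(u) for u in nodes]
    )


def read_connectome(
    path, fmt: str = "dense", directed: bool = False
) -> WeightedConnectome:
    """Read a weighted connectome; ``fmt``: dense | edgelist | graphml."""
    path = Path(path)
    if fmt == "dense":
        return _read_dense(path, directed)
    if fmt == "edgelist":
        return _read_edgelist_connectome(path, directed)
    if fmt == "graphml":
        return _read_graphml_connectome(path, directed)
    raise ValueError(f"unknown connectome format {fmt!r}")


def read_graph(path, fmt: Optional[str] = None) -> BinaryGraph:
    """Read a binary graph from GraphML or a 2-column edge-list TSV."""
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "edgelist"
    if fmt == "graphml":
        G = nx.read_graphml(path)
        nodes = list(G.nodes())
        try:  # GraphML stores ids as strings; recover integer node indices
            ids = {u: int(u) for u in nodes}
        except ValueError:
            order = sorted(nodes, key=lambda s: (len(str(s)), str(s)))
            ids = {u: i for i, u in enumerate(order)}
        n = max(ids.values(), default=-1) + 1
        edges = [(ids[u], ids[v]) for u, v in G.edges()]
        return BinaryGraph(n, edges, directed=G.is_directed())
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#", usecols=[0, 1])
    edges = [(int(a), int(b)) for a, b in df.itertuples(index=False)]
    n = max((max(u, v) for u, v in edges), default=-1) + 1
    return BinaryGraph(n, edges)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_graph(g: BinaryGraph, path, fmt: Optional[str] = None) -> None:
    """Write a binary graph as GraphML or a 2-column edge-list TSV."""
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "edgelist"
    if fmt == "graphml":
        nx.write_graphml(g.to_networkx(), path)
        return
    lines = [f"{u}\t{v}" for u, v in g.sorted_links()]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def write_connectome(w: WeightedConnectome, path) -> None:
    """Write a dense weighted matrix as TSV (header/index iff labeled)."""
    path = Path(path)
    sep = _delimiter_for(path)
    if w.node_labels is not None:
        df = pd.DataFrame(w.weights, index=w.node_labels, columns=w.node_labels)
        df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)
    else:
        np.savetxt(path, w.weights, delimiter=sep, fmt=_FLOAT_FMT)


def write_profile(profile, path) -> None:
    """Serialize a JProfile as TSV with columns m, rho, eg, el, j."""
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_partition(p: Partition, path) -> None:
    """Two-column TSV: node index, community label."""
    lines = ["node\tcommunity"]
    lines += [f"{i}\t{c}" for i, c in enumerate(p.assignment)]
    Path(path).write_text("\n".join(lines) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(report, path) -> None:
    """Write a report (dict or ComparisonReport) as deterministic JSON."""
    if hasattr(report, "to_json_dict"):
        report = report.to_json_dict()
    Path(path).write_text(json.dumps(report, indent=1, default=_json_default) + "\n")
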