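"""Between-sample distances on graph quantities.

Two normalized metrics, both in [0, 1] and zero exactly on identical
inputs:

* the Mirkin index between two node partitions — a pair-counting distance
  (2(n01 + n10) over the n(n-1) ordered pairs), equivalently the
  normalized Hamming distance between the pair-coincidence indicator
  vectors; a genuine metric on partitions;
* the divergent coefficient between nonnegative feature vectors —
  sqrt(mean(((x_u - x_v)/(x_u + x_v))^2)), an L2-type distance with a
  per-coordinate ratio normalization (Clark's divergence), a metric for
  positive features.

Scalars (Eg, El, Q) are compared with M = 1, per-node vectors (degree,
betweenness) with M = n, partitions with the Mirkin index.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
import pandas as pd

from .cohort import SampleFeatures
from .partitioning import Partition

__all__ = ["mirkin_index", "divergent_coefficient", "between_group_distances"]

_SCALAR_QUANTITIES = ("eg", "el", "q", "j", "largest_component")
_VECTOR_QUANTITIES = ("degree", "betweenness")


def _labels_of(p) -> np.ndarray:
    if isinstance(p, Partition):
        return np.asarray(p.assignment, dtype=np.intp)
    return np.asarray(list(p), dtype=np.intp)


def mirkin_index(pu, pv) -> float:
    """Normalized Mirkin distance between two partitions of the same nodes.

    0 for identical clusterings, 1 for the all-singletons vs. all-in-one
    extreme.  Computed from the contingency table: with same_u (same_v) the
    number of co-clustered pairs under each partition and ``both`` the
    pairs co-clustered under both, MI = 2(same_u + same_v - 2 both)/n(n-1).
    """
    lu, lv = _labels_of(pu), _labels_of(pv)
    if len(lu) != len(lv):
        raise ValueError("partitions must cover the same node set")
    n = len(lu)
    if n < 2:
        raise ValueError("Mirkin index requires at least 2 nodes")

    def _pairs(counts):
        c = np.asarray(counts, dtype=np.int64)
        return int((c * (c - 1) // 2).sum())

    same_u = _pairs(np.unique(lu, return_counts=True)[1])
    same_v = _pairs(np.unique(lv, return_counts=True)[1])
    joint = pd.crosstab(pd.Series(lu), pd.Series(lv)).to_numpy()
    both = _pairs(joint.ravel())
    return 2.0 * (same_u + same_v - 2 * both) / (n * (n - 1))


def divergent_coefficient(xu, xv) -> float:
    """Clark's divergence between nonnegative feature vectors of equal length.

    Coordinates where both entries are zero contribute nothing; the result
    is 0 iff the vectors are identical and 1 when supports are disjoint.
    """
    xu = np.asarray(xu, dtype=float).ravel()
    xv = np.asarray(xv, dtype=float).ravel()
    if xu.shape != xv.shape or xu.size < 1:
        raise ValueError("feature vectors must share a length M >= 1")
    if np.any(xu < 0) or np.any(xv < 0):
        raise ValueError("divergent coefficient requires nonnegative features")
    denom = xu + xv
    num = xu - xv
    ratio = np.divide(num, denom, out=np.zeros_like(denom), where=denom > 0)
    return float(np.sqrt(np.mean(ratio**2)))


def _pair_distance(fu: SampleFeatures, fv: SampleFeatures, quantity: str) -> float:
    if quantity == "partition":
        if fu.partition is None or fv.partition is None:
            raise ValueError("partition feature missing for a sample")
        return mirkin_index(fu.partition, fv.partition)
    if quantity in _VECTOR_QUANTITIES:
        return divergent_coefficient(getattr(fu, quantity), getattr(fv, quantity))
    if quantity in _SCALAR_QUANTITIES:
        a, b = getattr(fu, quantity), getattr(fv, quantity)
        if a is None or b is None:
            raise ValueError(f"feature {quantity!r} missing for a sample")
        return divergent_coefficient([a], [b])
    raise ValueError(f"unknown quantity {quantity!r}")


def between_group_distances(
    features: Dict[str, List[SampleFeatures]], quantity: str
) -> pd.DataFrame:
    """Cross-group distance table: one row per (group-1, group-2) sample pair.

    Mirkin index for partitions, divergent coefficient otherwise (M = 1
    for the scalar quantities Eg, El, Q; M = n for degree and betweenness
    vectors).
    """
    labels = list(features)
    if len(labels) != 2:
        raise ValueError("between-group distances need exactly two groups")
    ga, gb = features[labels[0]], features[labels[1]]
    rows = []
    for fu in ga:
        for fv in gb:
            rows.append(
                {
                    "sample_u": fu.sample_id,
                    "sample_v": fv.sample_id,
                    "quantity": quantity,
                    "distance": _pair_distance(fu, fv, quantity),
                }
            )
    return pd.DataFrame(rows)
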