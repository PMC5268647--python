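"""Shared dataclasses for synthetic cohorts and per-sample features.

A cohort study mimics the two-group (e.g. healthy vs. diseased) design of
imaging-connectome benchmarks: two labeled groups of weighted connectomes
generated from known topological models, so that the between-group
contrast is controlled by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .filtering import WeightedConnectome
from .partitioning import Partition

__all__ = ["ModelSpec", "CohortSpec", "CohortStudy", "SampleFeatures"]


@dataclass(frozen=True)
class ModelSpec:
    """Recipe for one synthetic network model instance.

    ``family`` is one of ``lattice``, ``er``, ``ws``, ``ba``.  Exactly one
    of ``k`` (average degree) or ``rho`` (density) fixes the link budget;
    ``p_ws`` and ``m_ba`` are the Watts-Strogatz rewiring probability and
    the Barabasi-Albert attachment count.
    """

    family: str
    n: int
    k: Optional[float] = None
    rho: Optional[float] = None
    p_ws: float = 0.1
    m_ba: int = 3
    directed: bool = False
    seed: Optional[int] = None

    def __post_init__(self):
        if self.family not in ("lattice", "er", "ws", "ba"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.n < 2:
            raise ValueError("model size must be at least 2")
        if (self.k is None) == (self.rho is None):
            raise ValueError("specify exactly one of k or rho")


@dataclass(frozen=True)
class CohortSpec:
    """Two labeled groups of weighted-connectome recipes sharing one size.

    Weights follow the planted scheme: links of the generated topology get
    weights uniform in [signal_low, 1], non-links uniform in
    (0, noise_high].  Defaults separate the two distributions so that
    density thresholding at the planted density recovers the topology.
    """

    group_a: ModelSpec
    group_b: ModelSpec
    samples_per_group: int = 10
    signal_low: float = 0.5
    noise_high: float = 0.3
    seed: Optional[int] = None
    labels: Tuple[str, str] = ("A", "B")

    def __post_init__(self):
        if self.group_a.n != self.group_b.n:
            raise ValueError("both cohort groups must share the same size n")
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be positive")


@dataclass
class CohortStudy:
    """Two labeled groups of weighted connectomes (the benchmark input)."""

    groups: Dict[str, List[WeightedConnectome]]
    spec: Optional[CohortSpec] = None

    def __post_init__(self):
        sizes = {w.n for samples in self.groups.values() for w in samples}
        if len(sizes) > 1:
            raise ValueError("all cohort samples must share the same size n")

    @property
    def n(self) -> int:
        for samples in self.groups.values():
            for w in samples:
                return w.n
        raise ValueError("empty cohort")

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(self.groups)


@dataclass
class SampleFeatures:
    """Graph quantities of one filtered sample, at all topological scales."""

    sample_id: str
    group: str
    eg: float
    el: float
    q: Optional[float]
    partition: Optional[Partition]
    degree: np.ndarray
    betweenness: np.ndarray
    largest_component: float
    j: Optional[float]

    def scalar(self, name: str) -> float:
        return getattr(self, name)
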