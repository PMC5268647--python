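"""The efficiency/cost quality function J and optimal-density search.

The quality of a binarized network at density rho is

    J = (Eg + El) / rho,

the efficiency gained per unit of wiring cost.  J -> 2 on complete graphs
(Eg = El = rho = 1) and J = 1 exactly on a perfect matching (Eg = rho =
1/(n-1), El = 0), the sparse triangle-free limit.  For ring lattices and
Erdos-Renyi graphs the density maximizing J follows rho = c/(n-1) with
c = 2 + sqrt(2) = 3.414 (lattices) and c = e = 2.718 (random graphs), so
the optimum sits near mean degree 3 regardless of topology.

This module provides J itself, its alpha-parametrized generalization
2[alpha*Eg + (1-alpha)*El]/rho, J profiles along strongest-first link
reinsertion, the two-step (quadratic-then-linear) density search used in
the simulations, and the continuous-degree optimizers of the asymptotic
forms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from ._util import pair_count, round_half_away
from .filtering import WeightedConnectome, rank_links
from .graph import BinaryGraph, density, global_efficiency, local_efficiency

__all__ = [
    "quality_j",
    "quality_j_alpha",
    "JProfile",
    "sweep_profile",
    "group_averaged_profile",
    "two_step_density_search",
    "lattice_asymptotic_local_efficiency",
    "lattice_optimal_degree",
    "random_graph_optimal_degree",
]


def quality_j(g: BinaryGraph) -> float:
    """J = (Eg + El) / rho.  Undefined (raises) on empty graphs."""
    if g.m == 0:
        raise ValueError("J is undefined at zero density (indefinite form)")
    return (global_efficiency(g) + local_efficiency(g)) / density(g)


def quality_j_alpha(g: BinaryGraph, alpha: float) -> float:
    """Parametrized J: 2[alpha*Eg + (1-alpha)*El]/rho; alpha=0.5 gives J."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if g.m == 0:
        raise ValueError("J is undefined at zero density (indefinite form)")
    eg = global_efficiency(g)
    el = local_efficiency(g)
    return 2.0 * (alpha * eg + (1.0 - alpha) * el) / density(g)


# ---------------------------------------------------------------------------
# asymptotic continuous-degree optima
# ---------------------------------------------------------------------------


def lattice_asymptotic_local_efficiency(k) -> float:
    """Large-n local efficiency of a ring lattice at mean degree k:
    El -> 3(k-2) / (4(k-1))."""
    k = np.asarray(k, dtype=float)
    return 3.0 * (k - 2.0) / (4.0 * (k - 1.0))


def lattice_optimal_degree() -> float:
    """Maximizer of the large-n lattice J over continuous mean degree.

    J ~ (n-1) * El_inf(k) / k, whose stationary condition k^2 - 4k + 2 = 0
    gives k = 2 + sqrt(2) = 3.414.  Solved numerically.
    """
    res = minimize_scalar(
        lambda k: -lattice_asymptotic_local_efficiency(k) / k,
        bounds=(2.0 + 1e-9, 12.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def random_graph_optimal_degree() -> float:
    """Maximizer of the large-n Erdos-Renyi J over continuous mean degree.

    Local efficiency vanishes and Eg scales as ln k / ln n, so
    J ~ (n-1) ln k / (k ln n); the maximizer of ln(k)/k is k = e = 2.718.
    """
    res = minimize_scalar(
        lambda k: -math.log(k) / k,
        bounds=(1.0 + 1e-9, 12.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# J profiles along strongest-first reinsertion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JProfile:
    """J (with Eg, El) recorded along a density sweep.

    ``rho`` is strictly increasing; ``argmax_*`` locate the recorded step
    with the highest J (first such step on exact ties).  ``argmax_k`` is
    the average-degree parametrization k = rho * (n - 1) used throughout.
    """

    n: int
    directed: bool
    m: np.ndarray
    rho: np.ndarray
    eg: np.ndarray
    el: np.ndarray
    j: np.ndarray

    def __post_init__(self):
        for name in ("m", "rho", "eg", "el", "j"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.rho) <= 0):
            raise ValueError("profile densities must be strictly increasing")

    def __len__(self):
        return len(self.m)

    @property
    def argmax_index(self) -> int:
        return int(np.argmax(self.j))

    @property
    def argmax_rho(self) -> float:
        return float(self.rho[self.argmax_index])

    @property
    def argmax_m(self) -> int:
        return int(self.m[self.argmax_index])

    @property
    def argmax_k(self) -> float:
        return self.argmax_rho * (self.n - 1)

    @property
    def argmax_j(self) -> float:
        return float(self.j[self.argmax_index])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"m": self.m.astype(int), "rho": self.rho, "eg": self.eg,
             "el": self.el, "j": self.j}
        )


def _profile_steps(n: int, directed: bool, max_links: int, stride: Optional[int]):
    if stride is None:
        stride = 1 if n <= 512 else math.ceil(max_links / 1000)
    eco_m = round_half_away(3 * n) if directed else round_half_away(1.5 * n)
    steps = set(range(1, max_links + 1, stride))
    steps.add(max_links)
    if eco_m <= max_links:
        steps.add(eco_m)
    return sorted(steps)


def sweep_profile(
    w: WeightedConnectome, stride: Optional[int] = None, mode: str = "raw"
) -> JProfile:
    """Reinsert links strongest-first and record (Eg, El, J) at each step.

    With the default stride every insertion is evaluated for n <= 512;
    larger networks are stride-sampled (ceil(max_links/1000)) with a forced
    evaluation at the ECO link count round(3n/2).
    """
    if w.n < 3:
        raise ValueError("sweep_profile requires at least 3 nodes")
    ranking = rank_links(w, mode)
    M = w.max_links
    steps = _profile_steps(w.n, w.directed, M, stride)
    ms, rhos, egs, els, js = [], [], [], [], []
    for m in steps:
        g = BinaryGraph(w.n, ranking.top(m), directed=w.directed)
        eg = global_efficiency(g)
        el = local_efficiency(g)
        rho = m / M
        ms.append(m)
        rhos.append(rho)
        egs.append(eg)
        els.append(el)
        js.append((eg + el) / rho)
    return JProfile(w.n, w.directed, np.array(ms), np.array(rhos),
                    np.array(egs), np.array(els), np.array(js))


def group_averaged_profile(
    cohort: Sequence[WeightedConnectome],
    stride: Optional[int] = None,
    mode: str = "raw",
) -> JProfile:
    """Average the J profile over a cohort at each link-count step.

    All samples must share size and directedness.  J is averaged across
    samples pointwise (Eg and El are averaged too, for reporting), and the
    maximum of the averaged profile defines the group-level optimum.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    n, directed = cohort[0].n, cohort[0].directed
    if any(w.n != n or w.directed != directed for w in cohort):
        raise ValueError("cohort samples must share size and directedness")
    profiles = [sweep_profile(w, stride=stride, mode=mode) for w in cohort]
    return JProfile(
        n,
        directed,
        profiles[0].m,
        profiles[0].rho,
        np.mean([p.eg for p in profiles], axis=0),
        np.mean([p.el for p in profiles], axis=0),
        np.mean([p.j for p in profiles], axis=0),
    )


# ---------------------------------------------------------------------------
# two-step optimal-density search
# ---------------------------------------------------------------------------


def _dedupe_by_m(rhos: np.ndarray, max_links: int, warn: bool) -> list:
    """Map candidate densities to distinct link counts m >= 1."""
    out = {}
    for rho in rhos:
        m = round_half_away(rho * max_links)
        if m >= 1:
            out[m] = m / max_links
    if warn and len(out) < len(rhos):
        warnings.warn(
            "density grid deduplicated: fewer distinct link counts than "
            "grid points at this network size",
            stacklevel=3,
        )
    return sorted(out.values())


def _argmax_j(
    sampler, n: int, rhos, rng, best: float, best_rho: float, prune: bool
):
    """Evaluate J over ascending densities, with the exact 2/rho bound.

    Since Eg + El <= 2, no graph at density rho can score above 2/rho;
    once that bound falls below the best J already seen, all remaining
    (denser) candidates are skipped.  This never changes the argmax for
    samplers that honour the requested density.
    """
    for rho in rhos:
        if prune and 2.0 / rho < best:
            break
        g = sampler(n, rho, rng)
        j = quality_j(g)
        if j >= best:
            best, best_rho = j, rho
    return best, best_rho


def two_step_density_search(
    model_sampler: Callable,
    n: int,
    replicates: int = 1,
    seed=None,
    grid_size: int = 100,
    prune: bool = True,
) -> np.ndarray:
    """Per-replicate J-maximizing density via the two-step grid search.

    Step 1 evaluates J on ``grid_size`` quadratically spaced densities
    rho_i = rho_max (i/grid)^2 (dense near zero, where the optimum lies);
    step 2 refines with ``grid_size`` linearly spaced values between the
    step-1 grid neighbours of the argmax.  The sampler is called as
    ``model_sampler(n, rho, rng)`` and may expose ``rho_max(n)`` to bound
    the admissible density interval (the pruned Barabasi-Albert model
    does).  Returns one optimal density per replicate.
    """
    if n < 3:
        raise ValueError("density search requires at least 3 nodes")
    rho_hi_fn = getattr(model_sampler, "rho_max", None)
    rho_hi = float(rho_hi_fn(n)) if callable(rho_hi_fn) else 1.0
    directed = bool(getattr(model_sampler, "directed", False))
    M = pair_count(n, directed)

    frac = (np.arange(1, grid_size + 1) / grid_size) ** 2
    grid1 = _dedupe_by_m(rho_hi * frac, M, warn=True)

    ss = np.random.SeedSequence(seed)
    optima = np.empty(replicates)
    for r, child in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(child)
        rep_fn = getattr(model_sampler, "for_replicate", None)
        sampler = rep_fn(n, rng) if callable(rep_fn) else model_sampler
        best, best_rho = _argmax_j(sampler, n, grid1, rng, -np.inf, np.nan, prune)
        # step 2: refine between the step-1 neighbours of the argmax
        pos = int(np.searchsorted(grid1, best_rho))
        lo = grid1[pos - 1] if pos > 0 else 1.0 / M
        hi = grid1[pos + 1] if pos + 1 < len(grid1) else rho_hi
        grid2 = _dedupe_by_m(np.linspace(lo, hi, grid_size), M, warn=False)
        best, best_rho = _argmax_j(sampler, n, grid2, rng, best, best_rho, prune)
        optima[r] = best_rho
    return optima
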