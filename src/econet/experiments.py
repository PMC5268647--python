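"""Orchestrated simulation experiments.

Two reproductions at desk scale:

* the density-scaling law — for each network family and size, find the
  J-maximizing density per replicate with the two-step search and fit the
  one-parameter power law rho = c/(n-1);
* the two-group cohort benchmark — filter every sample at a grid of
  density thresholds (and with the MST/PMFG/MST+ECO comparison methods),
  compute graph quantities at all scales, measure cross-group distances,
  and test the effect of threshold/method with a Kruskal-Wallis omnibus
  (alpha = 0.01) followed by Tukey-Kramer post-hoc comparisons on ranks
  (alpha = 0.05), plus per-threshold rank-sum tests on the largest
  component fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._util import as_rng, round_half_away, spawn_seed
from .cohort import CohortStudy, SampleFeatures
from .distances import between_group_distances
from .filtering import (
    WeightedConnectome,
    eco_filter,
    mst_eco_filter,
    mst_filter,
    pmfg_filter,
    threshold_by_density,
)
from .generators import ba_network, density_sampler, remove_random_links, watts_strogatz
from .graph import (
    BinaryGraph,
    betweenness_vector,
    degree_vector,
    global_efficiency,
    largest_component_fraction,
    local_efficiency,
)
from .partitioning import spectral_partition
from .quality import quality_j, two_step_density_search

__all__ = [
    "fit_power_law",
    "ScalingResult",
    "scaling_experiment",
    "optimal_degree_search",
    "apply_filter",
    "compute_sample_features",
    "ComparisonReport",
    "threshold_comparison",
]

DEFAULT_SIZES = (8, 16, 32, 64, 128, 256, 512)
DEFAULT_FAMILIES = ("lattice", "er", "ws", "ba")


# ---------------------------------------------------------------------------
# density-scaling law
# ---------------------------------------------------------------------------


def fit_power_law(points: Iterable[Tuple[float, float]]) -> Tuple[float, float]:
    """Least-squares fit of rho = c/(n-1); returns (c, adjusted R^2).

    The model is linear in x = 1/(n-1), so the closed form is
    c = sum(rho x)/sum(x^2).  Adjusted R^2 uses one model parameter.
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("power-law fit needs at least 2 points")
    n = np.array([p[0] for p in pts], dtype=float)
    rho = np.array([p[1] for p in pts], dtype=float)
    if np.unique(n).size < 2:
        raise ValueError("power-law fit is rank-deficient: all sizes equal")
    x = 1.0 / (n - 1.0)
    c = float(np.sum(rho * x) / np.sum(x * x))
    resid = rho - c * x
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((rho - rho.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    big_n = len(pts)
    if big_n > 2:
        r2 = 1.0 - (1.0 - r2) * (big_n - 1) / (big_n - 2)
    return c, r2


@dataclass
class ScalingResult:
    """Replicate optimal densities per (family, size) plus power-law fits."""

    densities: Dict[str, Dict[int, np.ndarray]]
    c: Dict[str, float]
    adjusted_r2: Dict[str, float]
    fit_on: str
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for family, per_size in self.densities.items():
            for n, rhos in per_size.items():
                for r, rho in enumerate(rhos):
                    rows.append(
                        {"family": family, "n": n, "replicate": r, "rho_opt": rho}
                    )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": list(self.c),
                "c": [self.c[f] for f in self.c],
                "adjusted_r2": [self.adjusted_r2[f] for f in self.c],
            }
        )


def scaling_experiment(
    families: Sequence[str] = DEFAULT_FAMILIES,
    sizes: Sequence[int] = DEFAULT_SIZES,
    replicates: int = 15,
    seed=None,
    fit_on: str = "means",
    grid_size: int = 100,
    p_ws: float = 0.1,
) -> ScalingResult:
    """Optimal-density scaling across families and sizes, with fits.

    Per (family, size), runs ``two_step_density_search`` over seeded
    replicates; the power law rho = c/(n-1) is fitted either to the
    per-size replicate means (default) or to all pooled replicate points.
    """
    if fit_on not in ("means", "pooled"):
        raise ValueError("fit_on must be 'means' or 'pooled'")
    master = as_rng(seed)
    densities: Dict[str, Dict[int, np.ndarray]] = {}
    c: Dict[str, float] = {}
    r2: Dict[str, float] = {}
    for family in families:
        sampler = density_sampler(family, p_ws=p_ws)
        per_size: Dict[int, np.ndarray] = {}
        for n in sizes:
            per_size[n] = two_step_density_search(
                sampler, n, replicates=replicates, seed=spawn_seed(master),
                grid_size=grid_size,
            )
        densities[family] = per_size
        if fit_on == "means":
            points = [(n, float(np.mean(r))) for n, r in per_size.items()]
        else:
            points = [(n, float(x)) for n, r in per_size.items() for x in r]
        c[family], r2[family] = fit_power_law(points)
    return ScalingResult(densities, c, r2, fit_on, seed)


def optimal_degree_search(
    family: str,
    n: int,
    degrees: Sequence[int] = (1, 2, 3, 4, 5, 6),
    n_seeds: int = 3,
    seed=None,
    p_ws: float = 0.1,
    m_ba: int = 3,
) -> Dict[str, object]:
    """Integer mean degree maximizing J, over seeded realizations.

    Follows the fixed-degree simulation protocol: Watts-Strogatz networks
    at each integer k (odd degrees via the odd-k lattice adjustment before
    rewiring) and Barabasi-Albert networks grown once per seed with
    ``m_ba`` attachment links then pruned at random to each target k.  BA
    growth yields mean degree 6 - 12/n (for m_ba = 3), so targets at or
    above that are evaluated on the unpruned network.
    """
    if family not in ("ws", "ba"):
        raise ValueError("optimal_degree_search supports the ws and ba families")
    master = as_rng(seed)
    argmax: List[int] = []
    j_table = np.empty((n_seeds, len(degrees)))
    for s in range(n_seeds):
        rng = np.random.default_rng(spawn_seed(master))
        base = ba_network(n, m_ba, seed=rng) if family == "ba" else None
        js = []
        for k in degrees:
            m_t = round_half_away(k * n / 2)
            if family == "ws":
                g = watts_strogatz(n, k, p_ws, seed=rng)
            else:
                g = remove_random_links(base, max(base.m - m_t, 0), rng)
            js.append(quality_j(g))
        j_table[s] = js
        argmax.append(int(degrees[int(np.argmax(js))]))
    return {
        "family": family,
        "degrees": tuple(degrees),
        "j": j_table,
        "argmax_per_seed": argmax,
        "argmax": int(np.bincount(argmax).argmax()),
    }


# ---------------------------------------------------------------------------
# cohort benchmark
# ---------------------------------------------------------------------------

FILTER_METHODS = ("density", "eco", "mst", "pmfg", "mst_eco")
QUANTITIES = ("eg", "el", "q", "partition", "degree", "betweenness")


def apply_filter(
    w: WeightedConnectome,
    method: str,
    k: Optional[float] = None,
    mode: str = "raw",
) -> BinaryGraph:
    """Dispatch to a filtering method; ``density`` takes a mean-degree k."""
    if method == "density":
        if k is None:
            raise ValueError("the density method needs a threshold k")
        return threshold_by_density(w, min(k / (w.n - 1), 1.0), mode=mode)
    if method == "eco":
        return eco_filter(w, mode=mode)
    if method == "mst":
        return mst_filter(w, mode=mode)
    if method == "pmfg":
        return pmfg_filter(w, mode=mode)
    if method == "mst_eco":
        return mst_eco_filter(w, mode=mode)
    raise ValueError(f"unknown filtering method {method!r}")


def compute_sample_features(
    g: BinaryGraph, sample_id: str, group: str
) -> SampleFeatures:
    """All graph quantities of one filtered sample."""
    has_links = g.m > 0
    partition = spectral_partition(g) if has_links else None
    return SampleFeatures(
        sample_id=sample_id,
        group=group,
        eg=global_efficiency(g),
        el=local_efficiency(g),
        q=partition.q if partition is not None else None,
        partition=partition,
        degree=degree_vector(g).values,
        betweenness=betweenness_vector(g).values,
        largest_component=largest_component_fraction(g),
        j=quality_j(g) if has_links else None,
    )


def _kruskal(groups: List[np.ndarray]) -> Tuple[float, float]:
    """Kruskal-Wallis H and p; degenerate all-identical data gives p = 1."""
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _tukey_on_ranks(
    values: np.ndarray, labels: np.ndarray, alpha: float
) -> pd.DataFrame:
    """All-pairs Tukey-Kramer comparison on rank-transformed values."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if np.all(values == values[0]):
        groups = pd.unique(labels)
        rows = [
            {"group_1": a, "group_2": b, "mean_rank_diff": 0.0,
             "p_adj": 1.0, "significant": False}
            for a, b in combinations(groups, 2)
        ]
        return pd.DataFrame(rows)
    ranks = stats.rankdata(values)
    res = pairwise_tukeyhsd(ranks, labels, alpha=alpha)
    pairs = list(combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "group_1": [a for a, _ in pairs],
            "group_2": [b for _, b in pairs],
            "mean_rank_diff": res.meandiffs,
            "p_adj": res.pvalues,
            "significant": res.reject,
        }
    )


@dataclass
class ComparisonReport:
    """Cohort benchmark output: features, distances and test summaries."""

    features: Dict[str, Dict[str, List[SampleFeatures]]]
    distances: pd.DataFrame
    omnibus_thresholds: pd.DataFrame
    posthoc_thresholds: Dict[str, pd.DataFrame]
    omnibus_methods: pd.DataFrame
    posthoc_methods: Dict[str, pd.DataFrame]
    lcc_tests: pd.DataFrame
    alpha_omnibus: float
    alpha_posthoc: float

    def to_json_dict(self) -> dict:
        return {
            "alpha_omnibus": self.alpha_omnibus,
            "alpha_posthoc": self.alpha_posthoc,
            "omnibus_thresholds": self.omnibus_thresholds.to_dict(orient="records"),
            "omnibus_methods": self.omnibus_methods.to_dict(orient="records"),
            "posthoc_thresholds": {
                q: df.to_dict(orient="records")
                for q, df in self.posthoc_thresholds.items()
            },
            "posthoc_methods": {
                q: df.to_dict(orient="records")
                for q, df in self.posthoc_methods.items()
            },
            "lcc_tests": self.lcc_tests.to_dict(orient="records"),
        }


def threshold_comparison(
    study: CohortStudy,
    thresholds: Sequence[int] = tuple(range(1, 13)),
    methods: Sequence[str] = ("eco", "mst", "pmfg", "mst_eco"),
    alpha_omnibus: float = 0.01,
    alpha_posthoc: float = 0.05,
    quantities: Sequence[str] = QUANTITIES,
    mode: str = "raw",
) -> ComparisonReport:
    """Benchmark thresholds and filtering methods on a two-group cohort.

    Conditions are the density thresholds k (rho = k/(n-1)) plus the
    requested methods.  For each condition and each graph quantity the
    cross-group distances are computed; Kruskal-Wallis omnibus tests ask
    whether the threshold (resp. method) affects the distances, and
    Tukey-Kramer post-hoc comparisons on ranks locate the specific pairs.
    A rank-sum test per threshold compares the largest-component fraction
    between groups.
    """
    if len(study.labels) != 2:
        raise ValueError("threshold_comparison needs a two-group cohort")
    conditions: List[Tuple[str, str, Optional[int]]] = [
        (f"k={k}", "density", k) for k in thresholds
    ]
    conditions += [(m, m, None) for m in methods]

    features: Dict[str, Dict[str, List[SampleFeatures]]] = {}
    for cond_label, method, k in conditions:
        per_group: Dict[str, List[SampleFeatures]] = {}
        for glabel, samples in study.groups.items():
            feats = []
            for idx, w in enumerate(samples):
                g = apply_filter(w, method, k=k, mode=mode)
                feats.append(compute_sample_features(g, f"{glabel}{idx}", glabel))
            per_group[glabel] = feats
        features[cond_label] = per_group

    dist_frames = []
    for cond_label, _, _ in conditions:
        for q in quantities:
            df = between_group_distances(features[cond_label], q)
            df.insert(0, "condition", cond_label)
            dist_frames.append(df)
    distances = pd.concat(dist_frames, ignore_index=True)

    threshold_labels = [f"k={k}" for k in thresholds]
    method_labels = list(methods)

    def _tests(cond_labels: List[str]):
        omni_rows = []
        posthoc: Dict[str, pd.DataFrame] = {}
        if len(cond_labels) < 2:  # nothing to compare
            return pd.DataFrame(columns=["quantity", "H", "p", "significant"]), posthoc
        for q in quantities:
            sub = distances[
                (distances["quantity"] == q)
                & (distances["condition"].isin(cond_labels))
            ]
            groups = [
                sub.loc[sub["condition"] == c, "distance"].to_numpy()
                for c in cond_labels
            ]
            h, p = _kruskal(groups)
            omni_rows.append(
                {"quantity": q, "H": h, "p": p, "significant": p < alpha_omnibus}
            )
            posthoc[q] = _tukey_on_ranks(
                sub["distance"].to_numpy(),
                sub["condition"].to_numpy(),
                alpha_posthoc,
            )
        return pd.DataFrame(omni_rows), posthoc

    omni_thr, post_thr = _tests(threshold_labels)
    omni_met, post_met = _tests(method_labels)

    la, lb = study.labels
    lcc_rows = []
    for cond_label, _, _ in conditions:
        a = np.array([f.largest_component for f in features[cond_label][la]])
        b = np.array([f.largest_component for f in features[cond_label][lb]])
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            u, p = math.nan, 1.0
        else:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        lcc_rows.append(
            {"condition": cond_label, "U": float(u), "p": float(p),
             "significant": p < alpha_omnibus}
        )
    lcc = pd.DataFrame(lcc_rows)

    return ComparisonReport(
        features=features,
        distances=distances,
        omnibus_thresholds=omni_thr,
        posthoc_thresholds=post_thr,
        omnibus_methods=omni_met,
        posthoc_methods=post_met,
        lcc_tests=lcc,
        alpha_omnibus=alpha_omnibus,
        alpha_posthoc=alpha_posthoc,
    )
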