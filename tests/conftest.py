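"""Shared fixtures and hypothesis configuration."""

import itertools
import tempfile

import numpy as np
import pytest
from hypothesis import HealthCheck, configuration, settings

# keep hypothesis's scratch storage out of the repository tree
configuration.set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hypothesis-"))

from econet import BinaryGraph

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    database=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def complete_graph(n: int, directed: bool = False) -> BinaryGraph:
    if directed:
        links = [(i, j) for i in range(n) for j in range(n) if i != j]
    else:
        links = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return BinaryGraph(n, links, directed=directed)


def matching_graph(n: int) -> BinaryGraph:
    assert n % 2 == 0
    return BinaryGraph(n, [(2 * i, 2 * i + 1) for i in range(n // 2)])


def all_pairs(n: int):
    return list(itertools.combinations(range(n), 2))


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def path3():
    return BinaryGraph(3, [(0, 1), (1, 2)])


@pytest.fixture
def triangle():
    return BinaryGraph(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def two_triangles():
    return BinaryGraph(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture
def star4():
    return BinaryGraph(4, [(0, 1), (0, 2), (0, 3)])


def random_graph(n: int, p: float, rng, directed: bool = False) -> BinaryGraph:
    pairs = (
        [(i, j) for i in range(n) for j in range(n) if i != j]
        if directed
        else all_pairs(n)
    )
    keep = rng.random(len(pairs)) < p
    return BinaryGraph(n, [pq for pq, k in zip(pairs, keep) if k], directed=directed)
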