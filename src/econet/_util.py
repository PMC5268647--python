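"""Small shared helpers: rounding, pair counts, RNG coercion."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["round_half_away", "pair_count", "as_rng", "spawn_seed"]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero.

    Used whenever a target density is converted into an integer link
    count, so that e.g. 3n/2 with n odd rounds up reproducibly.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def pair_count(n: int, directed: bool) -> int:
    """Number of candidate links among ``n`` nodes (no self-pairs)."""
    return n * (n - 1) if directed else n * (n - 1) // 2


def as_rng(seed) -> np.random.Generator:
    """Coerce ``seed`` (None, int, SeedSequence or Generator) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seed(rng: np.random.Generator) -> int:
    """Draw a child seed below 2**31 (safe for libraries expecting C longs)."""
    return int(rng.integers(2**31))
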