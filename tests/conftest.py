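"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from presee.geometry import DistanceWeights, TimePoint
from presee import mdl


@pytest.fixture
def weights() -> DistanceWeights:
    return DistanceWeights()


def make_points(coords) -> list[TimePoint]:
    return [TimePoint(float(a), float(b)) for a, b in coords]


def exhaustive_optimum(points, w: DistanceWeights) -> float:
    """True minimum total MDL cost over all character-point subsets.

    Enumerates every subset of interior points (endpoints always included) and
    sums ``mdl_seg`` over consecutive character pairs — the brute-force
    counterpart of the greedy scan, tractable for windows of about 12 points.
    """
    n = len(points)
    pair_cost: dict[tuple[int, int], float] = {}

    def cost(i: int, j: int) -> float:
        key = (i, j)
        if key not in pair_cost:
            pair_cost[key] = mdl.mdl_seg(points, i, j, w)
        return pair_cost[key]

    best = math.inf
    interior = range(1, n - 1)
    for r in range(n - 1):
        for subset in itertools.combinations(interior, r):
            chars = (0, *subset, n - 1)
            total = sum(cost(a, b) for a, b in zip(chars, chars[1:]))
            if total < best:
                best = total
    return best


def greedy_total_cost(points, projections, w: DistanceWeights) -> float:
    """Total MDL cost of a given segmentation, via the reference mdl module."""
    return sum(
        mdl.mdl_seg(points, a, b, w)
        for a, b in zip(projections, projections[1:])
    )


def random_window(rng: np.random.Generator, max_n: int = 12) -> list[TimePoint]:
    """A small random window with varied spacing and amplitude regimes."""
    n = int(rng.integers(2, max_n + 1))
    x = np.cumsum(rng.integers(1, 5, size=n)).astype(float)
    scale = float(rng.choice([0.3, 2.0, 15.0, 200.0]))
    y = np.cumsum(rng.normal(0.0, scale, size=n))
    return make_points(zip(x, y))
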