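"""MDL/MML code lengths for piecewise-linear segmentation.

The segmentation hypothesis H is the set of retained character points; the data
term encodes how far the original lines deviate from the covering segments.
For one candidate segment over points ``i..j``:

* ``hypothesis_cost``  — ``log2(len(segment(points[i], points[j])))`` bits;
* ``data_cost``        — for every original line ``k, k+1`` under the segment,
  ``log2(wp * d_p) + log2(wa * d_a)`` bits;
* ``mdl_seg``          — L(H) + L(S|H) with ``(i, j)`` as character points;
* ``mdl_noseg``        — L(H) of keeping every original line, i.e. the sum of
  ``log2(len)`` over lines ``i..j-1`` (no data term: the model is the data);
* ``prefer_segment``   — the greedy criterion ``mdl_seg < mdl_noseg`` (strict;
  a tie means "do not segment").

Every ``log2`` argument (a length or a weighted distance) is clamped below at
1, so each code-length term is >= 0 and vanishing segments are never rewarded.
Costs are in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .geometry import (
    DistanceWeights,
    Segment,
    TimePoint,
    angle_distance,
    perpendicular_distance,
)

__all__ = [
    "MdlCost",
    "hypothesis_cost",
    "data_cost",
    "mdl_seg",
    "mdl_noseg",
    "prefer_segment",
]


@dataclass(frozen=True)
class MdlCost:
    """Code length split into hypothesis and data-given-hypothesis bits."""

    lh: float
    ld: float

    @property
    def total(self) -> float:
        return self.lh + self.ld


def _log2_clamped(v: float) -> float:
    return math.log2(v) if v > 1.0 else 0.0


def _check_span(points: Sequence[TimePoint], i: int, j: int) -> None:
    if not (0 <= i < j < len(points)):
        raise IndexError(f"invalid span ({i}, {j}) for {len(points)} points")


def hypothesis_cost(points: Sequence[TimePoint], i: int, j: int) -> float:
    """Bits to encode the candidate segment ``points[i] -> points[j]``."""
    _check_span(points, i, j)
    return _log2_clamped(Segment(points[i], points[j]).length)


def data_cost(
    points: Sequence[TimePoint], i: int, j: int, w: DistanceWeights
) -> float:
    """Bits to encode the original lines ``i..j-1`` given the candidate segment.

    Zero when every interior point is collinear with the candidate.
    """
    _check_span(points, i, j)
    cand = Segment(points[i], points[j])
    total = 0.0
    for k in range(i, j):
        line = Segment(points[k], points[k + 1])
        total += _log2_clamped(w.wp * perpendicular_distance(line, cand))
        total += _log2_clamped(w.wa * angle_distance(line, cand))
    return total


def mdl_seg(points: Sequence[TimePoint], i: int, j: int, w: DistanceWeights) -> float:
    """Total code length treating ``i`` and ``j`` as the only character points."""
    return hypothesis_cost(points, i, j) + data_cost(points, i, j, w)


def mdl_seg_cost(
    points: Sequence[TimePoint], i: int, j: int, w: DistanceWeights
) -> MdlCost:
    """Like :func:`mdl_seg` but returning the (L(H), L(S|H)) split."""
    return MdlCost(hypothesis_cost(points, i, j), data_cost(points, i, j, w))


def mdl_noseg(points: Sequence[TimePoint], i: int, j: int) -> float:
    """Code length of keeping every original line between ``i`` and ``j``."""
    _check_span(points, i, j)
    total = 0.0
    for k in range(i, j):
        total += _log2_clamped(Segment(points[k], points[k + 1]).length)
    return total


def prefer_segment(
    points: Sequence[TimePoint], i: int, j: int, w: DistanceWeights
) -> bool:
    """True iff replacing lines ``i..j-1`` by one segment shortens the code.

    Strict inequality: at ``j == i + 1`` the two costs coincide and the answer
    is False.
    """
    return mdl_seg(points, i, j, w) < mdl_noseg(points, i, j)
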