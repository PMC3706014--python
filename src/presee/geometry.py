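"""Line geometry for time-series segmentation.

A scalar time series is viewed as a polyline: consecutive observations
``(index, value)`` define *original lines*, and a candidate segment joining two
non-adjacent observations approximates the original lines it spans.  The
quality of that approximation is measured by the *segmenting distance*, a
Hausdorff-style weighted sum of two components:

* **perpendicular distance** ``d_p`` — how far the endpoints of an original
  line lie from the (infinite) line through the candidate segment, combined as
  ``(l1**2 + l2**2) / (l1 + l2)``;
* **angle distance** ``d_a`` — ``len(L_o) * sin(theta)`` where ``theta`` is the
  smaller intersection angle between the two lines.

Distances are measured to the infinite line through the candidate, not clipped
to the segment body.  Internally the point-to-line and angle computations use
the vector/cross-product form, which is algebraically identical to the
slope/intercept form wherever the latter is defined but remains stable for
steep candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TimePoint",
    "Segment",
    "DistanceWeights",
    "DegenerateSegmentError",
    "perpendicular_offsets",
    "perpendicular_distance",
    "angle_distance",
    "segmenting_distance",
]


class DegenerateSegmentError(ValueError):
    """Raised when a candidate segment has zero index extent (vertical line)."""


@dataclass(frozen=True, order=True)
class TimePoint:
    """One observation of a stream: a serial/time coordinate and a value."""

    index: float
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.index):
            raise ValueError(f"non-finite index: {self.index!r}")


@dataclass(frozen=True)
class Segment:
    """A directed line between two stream points.

    Serves both as an *original line* (two consecutive observations) and as a
    *candidate segment* (two character-point candidates).  A candidate must
    have ``start.index < end.index``; an original line may be degenerate
    (repeated point), in which case its length is zero.
    """

    start: TimePoint
    end: TimePoint

    def __post_init__(self) -> None:
        if self.start.index > self.end.index:
            raise ValueError("segment start.index must be <= end.index")

    @property
    def dx(self) -> float:
        return self.end.index - self.start.index

    @property
    def dy(self) -> float:
        return self.end.value - self.start.value

    @property
    def length(self) -> float:
        """Euclidean length in the (index, value) plane."""
        return math.hypot(self.dx, self.dy)


@dataclass(frozen=True)
class DistanceWeights:
    """Weights (wp, wa) mixing perpendicular and angle distance; must sum to 1."""

    wp: float = 0.5
    wa: float = 0.5

    def __post_init__(self) -> None:
        if self.wp < 0 or self.wa < 0:
            raise ValueError("distance weights must be non-negative")
        if abs(self.wp + self.wa - 1.0) > 1e-12:
            raise ValueError(f"wp + wa must equal 1, got {self.wp + self.wa}")


def _point_line_distance(p: TimePoint, ls: Segment) -> float:
    # |cross(ls_vec, p - ls.start)| / len(ls); equals |k*x - y + b| / sqrt(k^2+1)
    # for a non-vertical ls with slope k, intercept b.
    denom = ls.length
    cross = ls.dx * (p.value - ls.start.value) - ls.dy * (p.index - ls.start.index)
    return abs(cross) / denom


def _require_candidate(ls: Segment) -> None:
    if ls.end.index - ls.start.index <= 0:
        raise DegenerateSegmentError(
            "candidate segment must span a positive index range"
        )


def perpendicular_offsets(lo: Segment, ls: Segment) -> tuple[float, float]:
    """Unsigned distances from the endpoints of ``lo`` to the line through ``ls``.

    Returns ``(l_p1, l_p2)`` for ``lo.start`` and ``lo.end`` respectively.

    Raises
    ------
    DegenerateSegmentError
        If ``ls`` has zero index extent (no finite slope).
    """
    _require_candidate(ls)
    return _point_line_distance(lo.start, ls), _point_line_distance(lo.end, ls)


def perpendicular_distance(lo: Segment, ls: Segment) -> float:
    """Perpendicular distance ``(l1**2 + l2**2) / (l1 + l2)``.

    The 0/0 case (both endpoints on the candidate line) is defined as 0.  The
    result always lies in ``[min(l1, l2), max(l1, l2)]``.
    """
    l1, l2 = perpendicular_offsets(lo, ls)
    s = l1 + l2
    if s == 0.0:
        return 0.0
    return (l1 * l1 + l2 * l2) / s


def angle_distance(lo: Segment, ls: Segment) -> float:
    """Angle distance ``len(lo) * sin(theta)``, ``theta`` the smaller angle.

    Computed as ``|cross(lo_vec, ls_vec)| / len(ls)``, which is 0 for parallel
    lines and for a zero-length ``lo``, and never exceeds ``len(lo)``.
    """
    _require_candidate(ls)
    cross = lo.dx * ls.dy - lo.dy * ls.dx
    return abs(cross) / ls.length


def segmenting_distance(lo: Segment, ls: Segment, w: DistanceWeights) -> float:
    """Weighted segmenting distance ``wp * d_p + wa * d_a``.

    Zero exactly when ``lo`` lies on the infinite line through ``ls``.
    """
    return w.wp * perpendicular_distance(lo, ls) + w.wa * angle_distance(lo, ls)
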