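"""Segmentation quality statistics: error rate, compress rate, threshold sweeps.

The *error rate* of a segmentation is the unweighted mean, over the segments
defined by consecutive character points, of the mean segmenting distance of
the original lines each segment covers::

    error_rate = (1/w) * sum_i (1/n_i) * sum_{line in segment_i} d(line, seg_i)

where ``w`` is the number of segments and ``n_i`` the number of original
lines spanned by segment ``i``.  A line on a segment boundary belongs to
exactly one segment — the one whose span covers it (only boundary *points*
are shared).  The *compress rate* is simply ``character points / stream
points``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .benchmark import bottom_up_positions
from .geometry import DistanceWeights, TimePoint
from .segmenter import CharacterPointSeq

__all__ = [
    "ErrorReport",
    "error_rate",
    "error_rate_arrays",
    "compress_rate",
    "threshold_sweep",
]


@dataclass(frozen=True)
class ErrorReport:
    """Error-rate summary of one segmentation."""

    error_rate: float
    n_segments: int
    compress_rate: float
    per_segment_errors: np.ndarray


def error_rate_arrays(
    x: np.ndarray,
    y: np.ndarray,
    char_positions: np.ndarray,
    w: DistanceWeights,
) -> ErrorReport:
    """Vectorized error rate from coordinate arrays and character positions.

    ``char_positions`` are sorted ordinal positions into ``x``/``y`` and must
    start at 0 and end at ``len(x) - 1``.
    """
    n = len(x)
    g = np.asarray(char_positions, dtype=np.int64)
    if len(g) < 2 or g[0] != 0 or g[-1] != n - 1:
        raise ValueError("character positions must span the whole series")
    if np.any(np.diff(g) <= 0):
        raise ValueError("character positions must be strictly increasing")

    # assign each original line k (points k, k+1) to the segment covering it
    k = np.arange(n - 1)
    seg = np.searchsorted(g, k, side="right") - 1

    a = g[seg]      # segment start position, per line
    c = g[seg + 1]  # segment end position, per line
    cdx = x[c] - x[a]
    cdy = y[c] - y[a]
    clen = np.hypot(cdx, cdy)

    def offset(p):
        return np.abs(cdx * (y[p] - y[a]) - cdy * (x[p] - x[a])) / clen

    l1 = offset(k)
    l2 = offset(k + 1)
    s = l1 + l2
    dp = np.where(s > 0.0, (l1 * l1 + l2 * l2) / np.where(s > 0.0, s, 1.0), 0.0)
    ldx = x[k + 1] - x[k]
    ldy = y[k + 1] - y[k]
    da = np.abs(ldx * cdy - ldy * cdx) / clen
    d = w.wp * dp + w.wa * da

    n_seg = len(g) - 1
    sums = np.bincount(seg, weights=d, minlength=n_seg)
    counts = np.bincount(seg, minlength=n_seg)
    per_seg = sums / counts
    return ErrorReport(
        error_rate=float(per_seg.mean()),
        n_segments=n_seg,
        compress_rate=len(g) / n,
        per_segment_errors=per_seg,
    )


def error_rate(
    points: Sequence[TimePoint],
    char_seq: CharacterPointSeq,
    w: DistanceWeights | None = None,
) -> ErrorReport:
    """Error rate of ``char_seq`` as a segmentation of ``points``."""
    if w is None:
        w = DistanceWeights()
    x = np.array([p.index for p in points], dtype=np.float64)
    y = np.array([p.value for p in points], dtype=np.float64)
    return error_rate_arrays(x, y, np.asarray(char_seq.projections), w)


def compress_rate(n_char: int, n_points: int) -> float:
    """Output size over input size: ``n_char / n_points``."""
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    return n_char / n_points


def threshold_sweep(
    points: Sequence[TimePoint],
    thresholds: Sequence[float],
    w: DistanceWeights | None = None,
) -> list[tuple[float, int]]:
    """Segment counts of bottom-up across merge thresholds.

    Returns ``(threshold, n_segments)`` pairs in input order; counts are
    non-increasing in the threshold.
    """
    if w is None:
        w = DistanceWeights()
    x = np.array([p.index for p in points], dtype=np.float64)
    y = np.array([p.value for p in points], dtype=np.float64)
    out = []
    for t in thresholds:
        pos = bottom_up_positions(x, y, w, error_threshold=float(t))
        out.append((float(t), len(pos) - 1))
    return out
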