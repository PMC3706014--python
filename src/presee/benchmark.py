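"""Bottom-up (BU) benchmark segmenter and its slide-window variant (SWBU).

BU starts from one segment per original line and repeatedly merges the
adjacent segment pair whose merged segment is cheapest, while that minimal
cost stays strictly below ``error_threshold``.  The merge cost is the mean
segmenting distance of the covered original lines to the merged segment — the
same unit as the segmenting error rate, so a threshold and an error rate are
directly comparable.  Ties are broken toward the leftmost pair, making the
output deterministic.

SWBU applies BU inside a fixed-capacity slide window: all character points of
a full window are emitted except the last, which seeds the next window.

BU cannot run on unbounded streams (it needs the whole series); the slide
window variant is the streaming benchmark.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .geometry import DistanceWeights, TimePoint
from .segmenter import CharacterPointSeq, SlideWindow, StreamOrderError

__all__ = ["BuConfig", "bottom_up", "bottom_up_positions", "swbu_stream"]


@dataclass(frozen=True)
class BuConfig:
    """Bottom-up tunables: merge threshold, window (SWBU only), weights."""

    error_threshold: float = 1.1
    window_size: int = 1000
    weights: DistanceWeights = field(default_factory=DistanceWeights)

    def __post_init__(self) -> None:
        if self.error_threshold < 0:
            raise ValueError("error_threshold must be >= 0")
        if self.window_size < 3:
            raise ValueError("window_size must be >= 3")


def _merge_cost(x: np.ndarray, y: np.ndarray, a: int, c: int, wp: float, wa: float) -> float:
    """Mean segmenting distance of original lines ``a..c-1`` to segment (a, c)."""
    cdx = x[c] - x[a]
    cdy = y[c] - y[a]
    clen = math.hypot(cdx, cdy)
    px = x[a : c + 1] - x[a]
    py = y[a : c + 1] - y[a]
    perp = np.abs(cdx * py - cdy * px) / clen
    l1 = perp[:-1]
    l2 = perp[1:]
    s = l1 + l2
    dp = np.where(s > 0.0, (l1 * l1 + l2 * l2) / np.where(s > 0.0, s, 1.0), 0.0)
    ldx = np.diff(px)
    ldy = np.diff(py)
    da = np.abs(ldx * cdy - ldy * cdx) / clen
    return float(np.mean(wp * dp + wa * da))


def bottom_up_positions(
    x: np.ndarray,
    y: np.ndarray,
    weights: DistanceWeights,
    error_threshold: float = math.inf,
    target_segments: int | None = None,
) -> np.ndarray:
    """Run bottom-up merging on arrays, returning surviving boundary positions.

    Merging stops when the cheapest merge reaches ``error_threshold`` (strict
    ``<`` to proceed) or, if ``target_segments`` is given, as soon as the
    segment count has been reduced to that target — the latter is how BU is
    count-matched against another segmenter without an explicit threshold
    sweep.
    """
    n = len(x)
    if n < 2:
        raise ValueError("bottom_up requires at least 2 points")
    wp, wa = weights.wp, weights.wa
    # doubly linked list over boundary positions 0..n-1
    prev = np.arange(-1, n - 1, dtype=np.int64)
    nxt = np.arange(1, n + 1, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    version = np.zeros(n, dtype=np.int64)
    n_segments = n - 1

    heap: list[tuple[float, int, int]] = []
    for b in range(1, n - 1):
        cost = _merge_cost(x, y, b - 1, b + 1, wp, wa)
        heap.append((cost, b, 0))
    heapq.heapify(heap)

    while heap:
        if target_segments is not None and n_segments <= target_segments:
            break
        cost, b, ver = heapq.heappop(heap)
        if not alive[b] or ver != version[b]:
            continue
        if target_segments is None and not cost < error_threshold:
            break
        a = int(prev[b])
        c = int(nxt[b])
        alive[b] = False
        nxt[a] = c
        prev[c] = a
        n_segments -= 1
        for mid in (a, c):
            if mid <= 0 or mid >= n - 1 or not alive[mid]:
                continue
            version[mid] += 1
            new_cost = _merge_cost(x, y, int(prev[mid]), int(nxt[mid]), wp, wa)
            heapq.heappush(heap, (new_cost, mid, int(version[mid])))

    return np.flatnonzero(alive)


def bottom_up(points: Sequence[TimePoint], cfg: BuConfig) -> CharacterPointSeq:
    """Bottom-up segmentation of a whole in-memory series."""
    x = np.array([p.index for p in points], dtype=np.float64)
    y = np.array([p.value for p in points], dtype=np.float64)
    pos = bottom_up_positions(x, y, cfg.weights, error_threshold=cfg.error_threshold)
    return CharacterPointSeq(
        points=[points[int(i)] for i in pos], projections=[int(i) for i in pos]
    )


def swbu_stream(
    source: Iterable[TimePoint], cfg: BuConfig
) -> Iterator[tuple[TimePoint, int]]:
    """Slide-window bottom-up over a stream, yielding ``(point, projection)``.

    Within each full window BU runs to its threshold; every resulting
    character point except the last is emitted and the last seeds the next
    window.  The final, possibly under-filled, window is flushed completely.
    """
    win = SlideWindow(cfg.window_size)
    it = iter(source)
    while True:
        full = win.refill(it)
        if win.size == 0:
            return
        if win.size == 1:
            yield (win.point(0), win.offset)
            return
        pos = bottom_up_positions(
            win.x[: win.size], win.y[: win.size], cfg.weights, cfg.error_threshold
        )
        if not full:
            for c in pos:
                yield (win.point(int(c)), win.offset + int(c))
            return
        for c in pos[:-1]:
            yield (win.point(int(c)), win.offset + int(c))
        win.slide_to(int(pos[-1]))
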