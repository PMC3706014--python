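"""Greedy MDL segmentation of a slide window and the PRESEE streaming driver.

The segmenter has two layers:

* :func:`segment_window` — one greedy pass over a buffered window (the
  in-window extraction step).  A candidate segment anchored at ``startIndex``
  grows one point at a time; while replacing the covered original lines by the
  single candidate shortens the MDL code (``mdl_seg < mdl_noseg``) it keeps
  growing, and on the first violation the previous point is emitted as a
  character point and the scan restarts there.  A candidate is only ever
  tested once it covers at least two original lines, since at a single line
  the two costs coincide by construction.  First and last window points are
  always character points.

* :func:`presee_stream` — the streaming driver.  It fills a fixed-capacity
  slide window from the source, runs the window pass, emits at most the first
  ``batch_size + 1`` character points, then slides the window so that the last
  emitted character point becomes its first element and refills.  If the
  window pass retains every point, no proper segment exists: the window is
  deemed random data, all its points are emitted and the window is emptied.
  Each source point is read exactly once and output starts while input is
  still being consumed, so downstream consumers can run concurrently.

Implementation notes.  The greedy scan is strictly left-to-right, so the first
``batch_size + 1`` character points of a window are already final the moment
they are found; the scan kernel therefore stops early once it has them *and*
has seen at least one successful merge (the merge evidence rules out the
all-points "random window" branch, which can only be decided by a complete
scan).  Costs are recomputed after every slide rather than cached.  The kernel
and the array driver are numba-compiled when numba is installed and run as
plain Python otherwise; both paths are identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._accel import njit
from .geometry import DistanceWeights, TimePoint

__all__ = [
    "SlideWindow",
    "CharacterPointSeq",
    "SegmenterConfig",
    "StreamOrderError",
    "segment_window",
    "presee_stream",
    "segment_series",
    "segment_file",
    "SegmentSummary",
]


class StreamOrderError(ValueError):
    """Raised when a source yields non-increasing indices."""


@dataclass(frozen=True)
class SegmenterConfig:
    """Tunables of the streaming segmenter.

    All of them are optional efficiency knobs; the defaults are the
    parameter-free operating point.

    window_size : capacity of the slide window (points), >= 3.
    batch_size  : character points emitted per full-window pass is at most
                  ``batch_size + 1``; larger batches slide the window further
                  per pass and run faster, without changing what is retained.
    weights     : perpendicular/angle mix of the segmenting distance.
    """

    window_size: int = 1000
    batch_size: int = 1
    weights: DistanceWeights = field(default_factory=DistanceWeights)

    def __post_init__(self) -> None:
        if self.window_size < 3:
            raise ValueError("window_size must be >= 3")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class CharacterPointSeq:
    """Ordered character points with their projection into the source stream.

    ``projections[i]`` is the 0-based ordinal position in the source stream of
    character point ``points[i]``; consecutive character points delimit one
    approximating segment.
    """

    points: list[TimePoint]
    projections: list[int]

    def __post_init__(self) -> None:
        if len(self.points) != len(self.projections):
            raise ValueError("points and projections must have equal length")
        for a, b in zip(self.projections, self.projections[1:]):
            if b <= a:
                raise ValueError("projections must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[TimePoint]:
        return iter(self.points)


# ---------------------------------------------------------------------------
# Greedy scan kernel
# ---------------------------------------------------------------------------


def _scan(x, y, lo, hi, wp, wa, max_chars):
    """Greedy character-point scan of the window ``x[lo:hi]``.

    Returns ``(positions, merge_seen, complete, ops)``: global character-point
    positions found so far, whether any candidate ever absorbed more than one
    line, whether the scan reached the end of the window, and the number of
    cost evaluations (for linear-scaling checks).

    The scan stops early once ``max_chars`` character points are known *and* a
    merge has been seen; a scan that completes with no merge retained every
    window point.  Every log2 argument is clamped below at 1, matching the
    mdl module.
    """
    n = hi - lo
    out = np.empty(n, np.int64)
    out[0] = lo
    m = 1
    merge_seen = False
    ops = 0
    noseg = 0.0
    start = lo
    cur = lo + 2
    while cur < hi:
        ops += 1
        if cur == start + 2:
            noseg = 0.0
            for k in range(start, start + 2):
                dx = x[k + 1] - x[k]
                dy = y[k + 1] - y[k]
                sq = dx * dx + dy * dy
                if sq > 1.0:
                    noseg += 0.5 * math.log2(sq)
        cdx = x[cur] - x[start]
        cdy = y[cur] - y[start]
        csq = cdx * cdx + cdy * cdy
        seg = 0.5 * math.log2(csq) if csq > 1.0 else 0.0
        if seg < noseg:
            clen = math.sqrt(csq)
            lp_prev = 0.0  # perpendicular offset of point `start`
            for k in range(start, cur):
                ops += 1
                cross = cdx * (y[k + 1] - y[start]) - cdy * (x[k + 1] - x[start])
                lp_next = abs(cross) / clen
                s = lp_prev + lp_next
                if s > 0.0:
                    dp = (lp_prev * lp_prev + lp_next * lp_next) / s
                else:
                    dp = 0.0
                ldx = x[k + 1] - x[k]
                ldy = y[k + 1] - y[k]
                da = abs(ldx * cdy - ldy * cdx) / clen
                v = wp * dp
                if v > 1.0:
                    seg += math.log2(v)
                v = wa * da
                if v > 1.0:
                    seg += math.log2(v)
                lp_prev = lp_next
                if seg >= noseg:
                    break
        if seg < noseg:
            # candidate keeps growing: the point at cur-1 will be skipped
            merge_seen = True
            if m >= max_chars:
                return out[:m], True, False, ops
            cur += 1
            if cur < hi:
                # the newly covered line is (cur-1, cur)
                dx = x[cur] - x[cur - 1]
                dy = y[cur] - y[cur - 1]
                sq = dx * dx + dy * dy
                if sq > 1.0:
                    noseg += 0.5 * math.log2(sq)
        else:
            out[m] = cur - 1
            m += 1
            start = cur - 1
            if m >= max_chars and merge_seen:
                return out[:m], True, False, ops
            cur += 1
    if out[m - 1] != hi - 1:
        out[m] = hi - 1
        m += 1
    return out[:m], merge_seen, True, ops


_scan_py = _scan
_scan = njit(cache=False)(_scan)


def _presee_positions(x, y, window, batch, wp, wa):
    """Whole-series slide-window driver over in-memory arrays.

    Returns the global character-point positions.  Identical, pass for pass,
    to the generic streaming driver; the window is a moving view on the
    arrays, so sliding costs nothing.
    """
    n = x.shape[0]
    out = np.empty(n, np.int64)
    m_out = 0
    lo = 0
    last = -1
    while lo < n:
        hi = lo + window
        if hi > n:
            hi = n
        size = hi - lo
        if size == 1:
            if lo > last:
                out[m_out] = lo
                m_out += 1
            break
        final = hi == n
        max_chars = size + 1 if final else batch + 1
        chars, merge_seen, complete, _ = _scan(x, y, lo, hi, wp, wa, max_chars)
        if final:
            for c in chars:
                if c > last:
                    out[m_out] = c
                    m_out += 1
                    last = c
            break
        if complete and chars.shape[0] == size:
            # no proper segment: pass the whole window through
            for c in range(lo, hi):
                if c > last:
                    out[m_out] = c
                    m_out += 1
                    last = c
            lo = hi
            continue
        stop = batch + 1
        if chars.shape[0] < stop:
            stop = chars.shape[0]
        for i in range(stop):
            c = chars[i]
            if c > last:
                out[m_out] = c
                m_out += 1
                last = c
        lo = int(chars[stop - 1])
    return out[:m_out]


_presee_positions = njit(cache=False)(_presee_positions)


def segment_window(
    points: Sequence[TimePoint], w: DistanceWeights | None = None
) -> CharacterPointSeq:
    """Run one greedy pass over a buffered window of points.

    Returns the character points with window-local projections.  Requires at
    least two points; the first and last are always retained.
    """
    if len(points) < 2:
        raise ValueError("segment_window requires at least 2 points")
    if w is None:
        w = DistanceWeights()
    x = np.array([p.index for p in points], dtype=np.float64)
    y = np.array([p.value for p in points], dtype=np.float64)
    pos, _, _, _ = _scan(x, y, 0, len(points), w.wp, w.wa, len(points) + 1)
    return CharacterPointSeq(
        points=[points[i] for i in pos], projections=[int(i) for i in pos]
    )


# ---------------------------------------------------------------------------
# Streaming driver
# ---------------------------------------------------------------------------


class SlideWindow:
    """Fixed-capacity buffer of contiguous stream points backed by numpy arrays.

    ``offset`` is the global ordinal position of slot 0.  Refilling validates
    strictly increasing indices; sliding retains a suffix in place.
    """

    def __init__(self, capacity: int):
        self.capacity = capacity
        self.x = np.empty(capacity, np.float64)
        self.y = np.empty(capacity, np.float64)
        self.size = 0
        self.offset = 0
        self._last_index = -math.inf

    def refill(self, it: Iterator[TimePoint]) -> bool:
        """Fill to capacity; returns False once the source is exhausted."""
        while self.size < self.capacity:
            try:
                p = next(it)
            except StopIteration:
                return False
            if not p.index > self._last_index:
                raise StreamOrderError(
                    f"stream indices must be strictly increasing: "
                    f"{p.index} after {self._last_index}"
                )
            self._last_index = p.index
            self.x[self.size] = p.index
            self.y[self.size] = p.value
            self.size += 1
        return True

    def slide_to(self, local_pos: int) -> None:
        """Retain the suffix starting at ``local_pos`` (which becomes slot 0)."""
        n = self.size - local_pos
        self.x[:n] = self.x[local_pos : self.size]
        self.y[:n] = self.y[local_pos : self.size]
        self.offset += local_pos
        self.size = n

    def clear(self) -> None:
        self.offset += self.size
        self.size = 0

    def point(self, local_pos: int) -> TimePoint:
        xi = self.x[local_pos]
        return TimePoint(int(xi) if float(xi).is_integer() else float(xi),
                         float(self.y[local_pos]))


def presee_stream(
    source: Iterable[TimePoint],
    cfg: SegmenterConfig | None = None,
    stats: dict | None = None,
) -> Iterator[tuple[TimePoint, int]]:
    """Segment a stream, yielding ``(character_point, projection)`` pairs.

    ``projection`` is the 0-based ordinal position of the character point in
    the source stream.  The source is scanned exactly once; memory is bounded
    by ``cfg.window_size``.  If ``stats`` is given it is populated with
    ``points_read``, ``points_emitted``, ``window_passes``, ``kernel_ops`` and
    ``buffer_high_water``.
    """
    if cfg is None:
        cfg = SegmenterConfig()
    wp, wa = cfg.weights.wp, cfg.weights.wa
    win = SlideWindow(cfg.window_size)
    it = iter(source)
    if stats is not None:
        stats.update(
            points_read=0,
            points_emitted=0,
            window_passes=0,
            kernel_ops=0,
            buffer_high_water=0,
        )
    last_emitted = -1  # global position of the last emitted point

    def _bump_read(prev_size: int) -> None:
        if stats is not None:
            stats["points_read"] += win.size - prev_size
            stats["buffer_high_water"] = max(stats["buffer_high_water"], win.size)

    def _emit(local_pos: int) -> tuple[TimePoint, int] | None:
        nonlocal last_emitted
        g = win.offset + local_pos
        if g <= last_emitted:
            return None
        last_emitted = g
        if stats is not None:
            stats["points_emitted"] += 1
        return (win.point(local_pos), g)

    while True:
        prev = win.size
        full = win.refill(it)
        _bump_read(prev)
        if win.size == 0:
            return
        if win.size == 1:
            out = _emit(0)
            if out is not None:
                yield out
            return
        max_chars = win.size + 1 if not full else cfg.batch_size + 1
        chars, merge_seen, complete, ops = _scan(
            win.x[: win.size], win.y[: win.size], 0, win.size, wp, wa, max_chars
        )
        if stats is not None:
            stats["window_passes"] += 1
            stats["kernel_ops"] += int(ops)
        if not full:
            # final (possibly under-filled) window: flush every character
            # point, including the stream's last point
            for c in chars:
                out = _emit(int(c))
                if out is not None:
                    yield out
            return
        if complete and len(chars) == win.size:
            # no proper segment exists: the window is deemed random data and
            # passed through unchanged
            for c in range(win.size):
                out = _emit(c)
                if out is not None:
                    yield out
            win.clear()
            continue
        emit_pos = chars[: cfg.batch_size + 1]
        for c in emit_pos:
            out = _emit(int(c))
            if out is not None:
                yield out
        win.slide_to(int(emit_pos[-1]))


def segment_series(
    points: Sequence[TimePoint] | tuple[np.ndarray, np.ndarray],
    cfg: SegmenterConfig | None = None,
) -> CharacterPointSeq:
    """Segment an in-memory series, identical in output to the streaming driver.

    Accepts either a sequence of :class:`TimePoint` or an ``(index, value)``
    array pair.  Uses the compiled whole-array driver, so large series run at
    kernel speed.
    """
    if cfg is None:
        cfg = SegmenterConfig()
    if isinstance(points, tuple):
        x = np.ascontiguousarray(points[0], dtype=np.float64)
        y = np.ascontiguousarray(points[1], dtype=np.float64)
        make = lambda i: TimePoint(  # noqa: E731
            int(x[i]) if float(x[i]).is_integer() else float(x[i]), float(y[i])
        )
    else:
        x = np.array([p.index for p in points], dtype=np.float64)
        y = np.array([p.value for p in points], dtype=np.float64)
        make = lambda i: points[i]  # noqa: E731
    if len(x) == 0:
        return CharacterPointSeq(points=[], projections=[])
    if np.any(np.diff(x) <= 0):
        raise StreamOrderError("indices must be strictly increasing")
    pos = _presee_positions(x, y, cfg.window_size, cfg.batch_size,
                            cfg.weights.wp, cfg.weights.wa)
    return CharacterPointSeq(
        points=[make(int(i)) for i in pos], projections=[int(i) for i in pos]
    )


@dataclass(frozen=True)
class SegmentSummary:
    """Bookkeeping from one file-to-file segmentation run."""

    n_in: int
    n_out: int

    @property
    def compress_rate(self) -> float:
        return self.n_out / self.n_in if self.n_in else 0.0


def segment_file(
    in_path,
    out_path,
    cfg: SegmenterConfig | None = None,
    include_projection: bool = False,
) -> SegmentSummary:
    """Stream a two-column file through the segmenter into an output file.

    Memory use is constant in the stream length (bounded by the window).
    """
    from .stream_io import StreamFileSpec, read_series, write_points

    stats: dict = {}
    spec = StreamFileSpec(path=in_path)
    with open(out_path, "w", encoding="utf-8") as sink:
        n_out = write_points(
            sink,
            presee_stream(read_series(spec), cfg, stats=stats),
            include_projection=include_projection,
        )
    return SegmentSummary(n_in=stats["points_read"], n_out=n_out)
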