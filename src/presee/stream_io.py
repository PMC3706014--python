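"""Readers and writers for headerless delimited stream files.

Two dialects are supported:

* ``index_value`` — two columns ``index,value`` (the native format of the
  synthetic generator and of typical sensor exports);
* ``value_only``  — one column of values; 0-based serial indices are assigned
  on read.

Reading is lazy (constant memory), validates strictly increasing indices, and
reports parse failures with the 1-based line number.  Writing round-trips:
``read_series`` of a ``write_points`` output reproduces the points exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .geometry import TimePoint
from .segmenter import StreamOrderError

__all__ = ["StreamFileSpec", "StreamParseError", "read_series", "write_points"]


class StreamParseError(ValueError):
    """Malformed stream-file row; carries the 1-based line number."""

    def __init__(self, path, line_number: int, message: str):
        super().__init__(f"{path}:{line_number}: {message}")
        self.path = path
        self.line_number = line_number


_DELIMITERS = {"comma": ",", "tab": "\t"}


@dataclass(frozen=True)
class StreamFileSpec:
    """Location and dialect of a stream file."""

    path: str | Path
    dialect: str = "index_value"
    delimiter: str = "comma"
    has_header: bool = False

    def __post_init__(self) -> None:
        if self.dialect not in ("index_value", "value_only"):
            raise ValueError(f"unknown dialect: {self.dialect!r}")
        if self.delimiter not in _DELIMITERS:
            raise ValueError(f"delimiter must be 'comma' or 'tab', got {self.delimiter!r}")


def _parse_number(token: str) -> float:
    v = float(token)
    return int(v) if v.is_integer() else v


def read_series(spec: StreamFileSpec) -> Iterator[TimePoint]:
    """Lazily yield the points of a stream file.

    Raises :class:`StreamParseError` on malformed rows and
    :class:`~presee.segmenter.StreamOrderError` on non-increasing indices.
    """
    delim = _DELIMITERS[spec.delimiter]
    prev_index = None
    serial = 0
    with open(spec.path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if spec.has_header and lineno == 1:
                continue
            line = raw.strip()
            if not line:
                continue
            fields = line.split(delim)
            try:
                if spec.dialect == "index_value":
                    if len(fields) < 2:
                        raise ValueError("expected two columns")
                    index = _parse_number(fields[0])
                    value = float(fields[1])
                else:
                    index = serial
                    value = float(fields[0])
            except ValueError as exc:
                raise StreamParseError(spec.path, lineno, str(exc)) from None
            if prev_index is not None and index <= prev_index:
                raise StreamOrderError(
                    f"{spec.path}:{lineno}: index {index} not greater than {prev_index}"
                )
            prev_index = index
            serial += 1
            yield TimePoint(index, value)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_points(
    sink: TextIO,
    points: Iterable[TimePoint | tuple[TimePoint, int]],
    include_projection: bool = False,
    delimiter: str = ",",
) -> int:
    """Write points (or ``(point, projection)`` pairs) as delimited rows.

    Returns the number of rows written.  The projection column is appended
    only when requested; bare points with ``include_projection=True`` are
    rejected.
    """
    n = 0
    for item in points:
        if isinstance(item, tuple):
            p, proj = item
        else:
            p, proj = item, None
        row = [_fmt(p.index), _fmt(p.value)]
        if include_projection:
            if proj is None:
                raise ValueError("projection requested but not available")
            row.append(str(int(proj)))
        sink.write(delimiter.join(row) + "\n")
        n += 1
    return n
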