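"""Bounded-random-walk generator for synthetic sensor-like streams.

Each record is ``(serial index, value)``.  The value performs a random walk
confined to ``[lb, ub]``: at every step a direction is drawn uniformly, the
step magnitude is a uniform 31-bit integer reduced modulo the integer distance
to the boundary in the chosen direction, and the result is scaled by
``sharpness``::

    delta = sign * (U mod max(1, floor(B))) * sharpness
    B     = (ub - previous)  if sign > 0 else  (previous - lb)

so steps shrink as the walk approaches a bound — the walk meets more
resistance the further it drifts from the midpoint ``(lb + ub) / 2``, which is
also the initial value.  Values are clamped to ``[lb, ub]`` after each step.
``sharpness`` scales the fluctuation power: at the standard configuration
(``lb=0, ub=3000, sharpness=0.001``) steps are uniform on roughly
``[-1.5, 1.5]`` value units per record.

The generator is fully deterministic under a fixed ``seed`` (PCG64); the
reproducibility contract is per-seed, not a specific bit stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ._accel import njit
from .geometry import TimePoint

__all__ = [
    "GeneratorConfig",
    "generate",
    "generate_arrays",
    "generate_stream",
    "write_stream",
    "table1_config",
    "STANDARD_CONFIGS",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the bounded random walk.

    size      : number of records to emit.
    lb, ub    : value bounds (source-stream units), lb < ub.
    sharpness : fluctuation power scaling each step, >= 0.
    seed      : RNG seed.
    """

    size: int
    lb: float = 0.0
    ub: float = 3000.0
    sharpness: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if not self.lb < self.ub:
            raise ValueError("lb must be < ub")
        if self.sharpness < 0:
            raise ValueError("sharpness must be >= 0")


def _walk(u, sign, lb, ub, sharpness, v0):
    """Advance the walk over pre-drawn step randomness; returns the values."""
    n = u.shape[0]
    out = np.empty(n, np.float64)
    prev = v0
    for i in range(n):
        if sign[i] > 0:
            bound = ub - prev
        else:
            bound = prev - lb
        m = int(bound)
        if m < 1:
            m = 1
        step = (u[i] % m) * sharpness
        if sign[i] > 0:
            prev = prev + step
        else:
            prev = prev - step
        if prev > ub:
            prev = ub
        elif prev < lb:
            prev = lb
        out[i] = prev
    return out


_walk = njit(cache=False)(_walk)

_CHUNK = 1_000_000


def generate_arrays(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate the full series as ``(index, value)`` arrays.

    Index is the 0-based record serial number; the first value is the midpoint
    ``(lb + ub) / 2``.
    """
    values = np.empty(cfg.size, np.float64)
    pos = 0
    for chunk in _value_chunks(cfg):
        values[pos : pos + len(chunk)] = chunk
        pos += len(chunk)
    return np.arange(cfg.size, dtype=np.float64), values


def _value_chunks(cfg: GeneratorConfig) -> Iterator[np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    v0 = 0.5 * (cfg.lb + cfg.ub)
    yield np.array([v0])
    remaining = cfg.size - 1
    prev = v0
    while remaining > 0:
        n = min(remaining, _CHUNK)
        u = rng.integers(0, 2**31, size=n, dtype=np.int64)
        sign = rng.integers(0, 2, size=n, dtype=np.int64) * 2 - 1
        chunk = _walk(u, sign, cfg.lb, cfg.ub, cfg.sharpness, prev)
        prev = chunk[-1]
        remaining -= n
        yield chunk


def generate(cfg: GeneratorConfig) -> list[TimePoint]:
    """Generate the series as a list of :class:`TimePoint` (small sizes)."""
    x, y = generate_arrays(cfg)
    return [TimePoint(int(a), float(b)) for a, b in zip(x, y)]


def generate_stream(cfg: GeneratorConfig) -> Iterator[TimePoint]:
    """Lazily yield the series point by point with chunked internal generation."""
    idx = 0
    for chunk in _value_chunks(cfg):
        for v in chunk:
            yield TimePoint(idx, float(v))
            idx += 1


def write_stream(cfg: GeneratorConfig, path, delimiter: str = ",") -> int:
    """Write the series to a headerless ``index,value`` file; returns row count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        idx = 0
        for chunk in _value_chunks(cfg):
            fh.writelines(
                f"{idx + k}{delimiter}{v:.6f}\n" for k, v in enumerate(chunk)
            )
            idx += len(chunk)
            n += len(chunk)
    return n


# (size, lb, ub, sharpness) of the eleven standard synthetic configurations
STANDARD_CONFIGS: dict[int, tuple[int, float, float, float]] = {
    1: (10_000, 0.0, 3000.0, 0.001),
    2: (100_000, 0.0, 3000.0, 0.001),
    3: (1_000_000, 0.0, 3000.0, 0.001),
    4: (10_000_000, 0.0, 3000.0, 0.001),
    5: (10_000_000, 0.0, 3000.0, 0.002),
    6: (10_000_000, 0.0, 3000.0, 0.0005),
    7: (10_000_000, 0.0, 3000.0, 0.0002),
    8: (10_000_000, 0.0, 3000.0, 0.0001),
    9: (100_000_000, 0.0, 3000.0, 0.00005),
    10: (1_000_000_000, 0.0, 5000.0, 0.00001),
    11: (10_000_000_000, 0.0, 5000.0, 0.00001),
}


def table1_config(dataset_number: int, seed: int = 0) -> GeneratorConfig:
    """Return the standard synthetic configuration ``1..11``."""
    try:
        size, lb, ub, sharp = STANDARD_CONFIGS[dataset_number]
    except KeyError:
        raise ValueError(
            f"dataset_number must be in 1..11, got {dataset_number}"
        ) from None
    return GeneratorConfig(size=size, lb=lb, ub=ub, sharpness=sharp, seed=seed)
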