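"""Optional numba acceleration for the hot per-window kernels.

The kernels are written as plain Python over numpy arrays and are compiled
with ``numba.njit`` when numba is importable; otherwise they run as-is.  Both
paths are numerically identical.
"""

from __future__ import annotations

try:  # pragma: no cover - exercised implicitly by whichever path is active
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def decorate(func):
            return func

        return decorate


__all__ = ["njit", "HAVE_NUMBA"]
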