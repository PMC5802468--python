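"""Optional numba acceleration.

All right-hand-side and tissue-stepping kernels are written in plain
numpy-scalar Python so they run unmodified with or without numba.  When
numba is importable the kernels are nopython-compiled; otherwise they fall
back to the interpreter (identical results, slower).
"""

from __future__ import annotations

try:  # pragma: no cover - environment dependent
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


__all__ = ["njit", "HAVE_NUMBA"]
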