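"""Optional numba acceleration with a transparent pure-Python fallback."""

from __future__ import annotations

try:  # pragma: no cover - exercised implicitly by every sampler call
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]) and not kwargs:
            return args[0]

        def wrap(func):
            return func

        return wrap
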