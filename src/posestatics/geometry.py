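"""Small planar geometry helpers shared across modules."""

from __future__ import annotations

import numpy as np

Point2 = np.ndarray  # shape (2,), float64


def as_point(p) -> Point2:
    """Coerce to a float64 (2,) array."""
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2-vector, got shape {a.shape}")
    return a


def cross2(r, f) -> float:
    """z-component of the planar cross product r x f (CCW-positive)."""
    r = np.asarray(r, dtype=float)
    f = np.asarray(f, dtype=float)
    return float(r[0] * f[1] - r[1] * f[0])
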