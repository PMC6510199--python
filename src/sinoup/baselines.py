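"""Analytic comparator for angular upsampling: per-column cubic interpolation.

Each detector column of the sinogram is treated as a 1-D signal along the
angle axis and interpolated with a cubic spline; only the angle axis is
upscaled, so no 2-D (bicubic) coupling between detector columns is used.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicHermiteSpline, CubicSpline

SPLINE_KINDS = ("not-a-knot", "natural", "catmull-rom")


def cubic_upscale(s: np.ndarray, factor: int, kind: str = "not-a-knot") -> np.ndarray:
    """Upscale an ``(L, W)`` sinogram along the angle axis by ``factor``.

    Evaluates ``factor − 1`` equispaced positions inside every gap; the
    original rows are preserved bit-exactly at their output slots (indices
    divisible by ``factor``).  ``kind`` selects the spline flavour:
    ``"not-a-knot"`` (default), ``"natural"``, or ``"catmull-rom"``
    (a local Hermite spline with centred-difference tangents).
    """
    s = np.asarray(s)
    if s.ndim != 2:
        raise ValueError("expected a 2-D sinogram (angle rows × detector columns)")
    L = s.shape[0]
    if L < 4:
        raise ValueError(f"cubic interpolation needs at least 4 rows, got {L}")
    if int(factor) != factor or factor < 2:
        raise ValueError(f"upscaling factor must be an integer ≥ 2, got {factor}")
    factor = int(factor)
    x = np.arange(L, dtype=np.float64)
    if kind == "catmull-rom":
        spline = CubicHermiteSpline(x, s, np.gradient(s, axis=0), axis=0)
    elif kind in ("not-a-knot", "natural"):
        spline = CubicSpline(x, s, axis=0, bc_type=kind)
    else:
        raise ValueError(f"unknown spline kind {kind!r}; choose from {SPLINE_KINDS}")
    xi = np.arange(factor * (L - 1) + 1, dtype=np.float64) / factor
    out = spline(xi).astype(s.dtype)
    out[::factor] = s  # kept rows pass through exactly
    return out
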