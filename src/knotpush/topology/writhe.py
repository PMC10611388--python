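"""Gauss-integral writhe of polygonal curves.

The writhe is the Gauss double integral of the curve over itself,

    Wr = (1/4pi) oint oint  (t1 x t2) . r12 / |r12|^3  ds1 ds2,

evaluated exactly as a sum of analytic solid-angle contributions over all
non-adjacent segment pairs (the numba kernel in :mod:`knotpush._core`).
Planar curves have writhe 0; mirroring negates it; the sign convention
matches crossing signs by the right-hand rule, so a right-handed trefoil
has Wr near +3.4.
"""

from __future__ import annotations

import numpy as np

from .._core import writhe_segments

__all__ = ["gauss_writhe"]


def gauss_writhe(vertices: np.ndarray, closed: bool = True) -> float:
    """Writhe of the polygonal curve through ``vertices``.

    For ``closed=True`` the segment from the last vertex back to the first
    is included (vertices must not duplicate the endpoint); open curves are
    evaluated as-is.  Zero-length segments contribute nothing.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 3:
        raise ValueError("vertices must be an (N, 3) array")
    if verts.shape[0] < 3:
        return 0.0
    return float(writhe_segments(verts, closed))
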