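"""Chain closure with the ligation filter.

Knots are defined on closed curves, so open simulation frames must be
closed before typing.  To keep the closure from injecting entanglements,
frames are only evaluated when the end-to-end distance is below a ligation
distance (10 sigma by default, matching the typical frame-to-frame
variation of the end-to-end distance); accepted frames are closed by the
minimally-interfering construction: both termini are pushed radially away
from the chain centroid onto a far sphere and joined by an arc on that
sphere, far outside the coil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClosedCurve", "ClosureError", "close_chain"]


class ClosureError(RuntimeError):
    """Closure could not achieve the required clearance from the chain."""


@dataclass(frozen=True)
class ClosedCurve:
    """Closed polygonal curve; original chain vertices come first."""

    vertices: np.ndarray          # (M, 3), no duplicated endpoint
    n_chain: int                  # leading vertices belonging to the chain
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.vertices.shape[0] < 3:
            raise ValueError("closed curve needs at least 3 vertices")

    @property
    def closure_vertices(self) -> np.ndarray:
        return self.vertices[self.n_chain:]


def _point_segment_distances(points: np.ndarray, a: np.ndarray,
                             b: np.ndarray) -> np.ndarray:
    """Min distance from each point to the closest of segments a[k]->b[k]."""
    ab = b - a                                    # (S, 3)
    ap = points[:, None, :] - a[None, :, :]       # (P, S, 3)
    denom = np.einsum("sd,sd->s", ab, ab) + 1e-30
    t = np.clip(np.einsum("psd,sd->ps", ap, ab) / denom, 0.0, 1.0)
    closest = a[None] + t[:, :, None] * ab[None]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def _min_clearance(closure_pts: np.ndarray, chain: np.ndarray) -> float:
    """Distance between the closure interior and the chain interior.

    The closure is attached to the chain termini, so samples within 1.5
    sigma of either attachment and the two terminal chain segments are
    excluded from the check; what remains is exactly the part of the
    closure that could entangle with the coil.
    """
    samples = []
    arc_pos = []
    travelled = 0.0
    for k in range(len(closure_pts) - 1):
        a, b = closure_pts[k], closure_pts[k + 1]
        seg_len = float(np.linalg.norm(b - a))
        n = max(2, int(seg_len / 0.2))
        ts = np.linspace(0.0, 1.0, n)
        samples.append(a[None] + ts[:, None] * (b - a)[None])
        arc_pos.append(travelled + ts * seg_len)
        travelled += seg_len
    pts = np.concatenate(samples)
    arc = np.concatenate(arc_pos)
    interior = (arc > 1.5) & (arc < travelled - 1.5)
    if not np.any(interior) or chain.shape[0] < 4:
        return np.inf
    a = chain[1:-2]
    b = chain[2:-1]
    if len(a) == 0:
        return np.inf
    return float(_point_segment_distances(pts[interior], a, b).min())


def close_chain(
    open_vertices: np.ndarray,
    ligation_distance: float = 10.0,
    clearance: float = 0.1,
    max_attempts: int = 5,
    provenance: str = "",
) -> ClosedCurve | None:
    """Close an open chain, or return None when the ligation filter rejects.

    Accepted chains are closed by extending both termini radially away from
    the centroid onto a sphere of three times the maximal centroid distance
    and connecting them along that sphere.  The added polyline must clear
    the chain by ``clearance``; blocked radial directions are nudged away
    from nearby chain beads before giving up with :class:`ClosureError`.
    """
    chain = np.asarray(open_vertices, dtype=float)
    if chain.shape[0] < 3:
        raise ValueError("need at least 3 vertices")
    e2e = float(np.linalg.norm(chain[-1] - chain[0]))
    if e2e > ligation_distance:
        return None
    if e2e < 1e-9:
        return ClosedCurve(chain[:-1].copy(), chain.shape[0] - 1, provenance)

    centroid = chain.mean(axis=0)
    radius = 3.0 * float(np.linalg.norm(chain - centroid, axis=1).max())

    def radial(v: np.ndarray) -> np.ndarray:
        d = v - centroid
        n = np.linalg.norm(d)
        if n < 1e-9:
            d, n = np.array([0.0, 0.0, 1.0]), 1.0
        return d / n

    dir_end = radial(chain[-1])
    dir_start = radial(chain[0])
    for attempt in range(max_attempts):
        a_end = centroid + radius * dir_end
        a_start = centroid + radius * dir_start
        # great-circle arc between the two sphere points
        u = dir_end
        w = dir_start
        cosang = float(np.clip(u @ w, -1.0, 1.0))
        ang = np.arccos(cosang)
        if ang < 1e-6:
            arc = np.empty((0, 3))
        else:
            n_arc = max(2, int(np.ceil(ang / 0.3)))
            ts = np.linspace(0.0, 1.0, n_arc + 1)[1:-1]
            sin_ang = np.sin(ang)
            arc = (
                centroid
                + radius
                * (
                    np.sin((1 - ts))[:, None] * 0.0
                    + (np.sin((1 - ts) * ang)[:, None] * u
                       + np.sin(ts * ang)[:, None] * w) / sin_ang
                )
            )
        closure = np.concatenate([[chain[-1]], [a_end], arc, [a_start],
                                  [chain[0]]])
        if _min_clearance(closure, chain) >= clearance:
            verts = np.concatenate([chain, closure[1:-1]])
            return ClosedCurve(verts, chain.shape[0], provenance)
        # nudge the radial directions away from the nearest chain beads
        for d, endpoint in ((dir_end, chain[-1]), (dir_start, chain[0])):
            near = chain[np.linalg.norm(chain - endpoint, axis=1) < 3.0]
            if len(near):
                away = endpoint - near.mean(axis=0)
                if np.linalg.norm(away) > 1e-9:
                    d += 0.5 * away / np.linalg.norm(away)
                    d /= np.linalg.norm(d)
    raise ClosureError(
        f"no closure with clearance {clearance} after {max_attempts} attempts"
    )
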