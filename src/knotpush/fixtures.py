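"""Deterministic curve generators with known ground-truth topology.

These stand in for expensive simulation output in tests and are the source
of the bundled identification table: every curve here has a knot type known
*by construction* (torus-knot parametrisation, figure-eight parametrisation,
or a rational-knot 4-plat assembled from a continued fraction), so the
topology pipeline can be validated against them end to end.

Handedness convention: a chiral fixture labelled "right" is the variant
whose spatial (Gauss-integral) writhe is positive; generators self-normalise
by mirroring z when needed, so the label can never silently disagree with
the geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ._core import writhe_segments

__all__ = [
    "FixtureCurve",
    "torus_knot_curve",
    "figure_eight_curve",
    "rational_knot_curve",
    "twist_knot_curve",
    "random_ring",
    "hairpin_chain",
    "RATIONAL_FRACTIONS",
]

# Canonical positive continued fractions of the 2-bridge (rational) knots
# bundled here; the list value [a1, ..., ak] encodes the alternating 4-plat
# with a1, a2, ... crossings per twist region.  The numerator of the
# continued fraction equals the knot determinant (checked at table build).
RATIONAL_FRACTIONS: dict[str, list[int]] = {
    "3_1": [3],
    "4_1": [2, 2],
    "5_1": [5],
    "5_2": [3, 2],
    "6_1": [4, 2],
    "6_2": [3, 1, 2],
    "6_3": [2, 1, 1, 2],
    "7_1": [7],
    "7_2": [5, 2],
    "7_3": [4, 3],
    "7_4": [3, 1, 3],
    "7_5": [3, 2, 2],
    "7_6": [2, 2, 1, 2],
    "7_7": [2, 1, 1, 1, 2],
    "8_1": [6, 2],
    "9_1": [9],
    "9_2": [7, 2],
}


@dataclass(frozen=True)
class FixtureCurve:
    """A closed polygonal curve with known topology (no duplicate endpoint)."""

    vertices: np.ndarray
    name: str
    handedness: str = "undetermined"   # left / right / amphichiral
    expected_writhe_sign: int = 0
    params: dict = field(default_factory=dict)

    @property
    def writhe(self) -> float:
        return float(writhe_segments(self.vertices, True))

    def mirrored(self) -> "FixtureCurve":
        v = self.vertices.copy()
        v[:, 2] *= -1.0
        flip = {"left": "right", "right": "left"}
        return FixtureCurve(
            v,
            self.name,
            flip.get(self.handedness, self.handedness),
            -self.expected_writhe_sign,
            dict(self.params),
        )


def _torus_name(p: int, q: int) -> str:
    key = tuple(sorted((p, q)))
    return {
        (2, 3): "3_1",
        (2, 5): "5_1",
        (2, 7): "7_1",
        (2, 9): "9_1",
        (3, 4): "8_19",
        (3, 5): "10_124",
    }.get(key, f"torus_{key[0]}_{key[1]}")


def torus_knot_curve(
    p: int = 2, q: int = 3, hand: str = "right", n_points: int = 400
) -> FixtureCurve:
    """Closed (p, q) torus knot; ``hand`` selects the mirror variant."""
    if math.gcd(p, q) != 1:
        raise ValueError(f"({p},{q}) with gcd != 1 is a link, not a knot")
    if p < 2 or q < 2:
        raise ValueError("need p, q >= 2")
    if hand not in ("left", "right"):
        raise ValueError("hand must be 'left' or 'right'")
    if n_points < 50 * (p + q):
        raise ValueError(f"n_points must be at least {50 * (p + q)}")
    phi = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    r = 2.0 + np.cos(q * phi)
    verts = np.column_stack(
        [r * np.cos(p * phi), r * np.sin(p * phi), np.sin(q * phi)]
    )
    wr = float(writhe_segments(verts, True))
    want = 1 if hand == "right" else -1
    if np.sign(wr) != want:
        verts[:, 2] *= -1.0
    return FixtureCurve(
        verts,
        _torus_name(p, q),
        hand,
        want,
        {"p": p, "q": q, "n_points": n_points},
    )


def figure_eight_curve(n_points: int = 400) -> FixtureCurve:
    """Closed figure-eight (4_1) knot; amphichiral."""
    if n_points < 200:
        raise ValueError("n_points must be at least 200")
    t = np.linspace(0.0, 2.0 * math.pi, n_points, endpoint=False)
    r = 2.0 + np.cos(2.0 * t)
    verts = np.column_stack(
        [r * np.cos(3.0 * t), r * np.sin(3.0 * t), np.sin(4.0 * t)]
    )
    return FixtureCurve(verts, "4_1", "amphichiral", 0, {"n_points": n_points})


def continued_fraction_value(quotients: list[int]) -> Fraction:
    """p/q of [a1, ..., ak] evaluated as ak + 1/(a(k-1) + 1/(... + 1/a1))."""
    val = Fraction(quotients[0])
    for a in quotients[1:]:
        val = a + 1 / val
    return val


def _odd_length(quotients: list[int]) -> list[int]:
    """Equivalent odd-length positive continued fraction ([.., a] -> [.., a-1, 1])."""
    q = list(quotients)
    if len(q) % 2 == 0:
        if q[-1] < 2:
            raise ValueError("cannot convert fraction ending in 1")
        q = q[:-1] + [q[-1] - 1, 1]
    return q


def rational_knot_curve(
    quotients: list[int] | str, jitter_seed: int = 7
) -> FixtureCurve:
    """Closed 3D curve of the 2-bridge knot with the given twist counts.

    Builds the standard 4-plat: four strands running along x, twisted
    pairwise region by region (middle pair for odd-numbered regions, bottom
    pair for even), capped at both ends.  Over/under is left arbitrary here;
    callers project along z and apply the alternating assignment to obtain
    the alternating diagram.  A tiny seeded vertex jitter removes the exact
    collinearities of the scaffold so the projection is generic.
    """
    if isinstance(quotients, str):
        name = quotients
        if name not in RATIONAL_FRACTIONS:
            raise KeyError(f"no bundled fraction for {name!r}")
        quotients = RATIONAL_FRACTIONS[name]
    else:
        name = "rational"
    if any(a < 1 for a in quotients):
        raise ValueError("partial quotients must be positive")
    word = _odd_length(quotients)
    p = continued_fraction_value(quotients).numerator
    if p % 2 == 0:
        raise ValueError("even numerator: this 4-plat closes to a 2-link")

    # four wires tracked by level (y = level); each crossing spans dx = 1
    paths: list[list[tuple[float, float, float]]] = [[] for _ in range(4)]
    at_level = [0, 1, 2, 3]  # wire index currently at each level
    x = 0.0
    for i in range(4):
        paths[i].append((x, float(i), 0.0))
    for region, a in enumerate(word):
        lo = 1 if region % 2 == 0 else 0  # middle pair first
        for _ in range(a):
            wa = at_level[lo]
            wb = at_level[lo + 1]
            ya, yb = float(lo), float(lo + 1)
            # alternating 4-plat: middle-pair regions put the upper entrant
            # on top, bottom-pair regions the lower entrant
            za = 0.5 if lo == 0 else -0.5
            # apex vertices offset from the midpoint; shadow stays an X
            paths[wa].append((x + 0.4, ya + 0.4 * (yb - ya), za))
            paths[wa].append((x + 1.0, yb, 0.0))
            paths[wb].append((x + 0.6, yb + 0.6 * (ya - yb), -za))
            paths[wb].append((x + 1.0, ya, 0.0))
            at_level[lo], at_level[lo + 1] = wb, wa
            x += 1.0
        # all wires advance to the current x
        for i in range(4):
            px, py, pz = paths[i][-1]
            if px < x:
                paths[i].append((x, py, pz))
    x_end = x

    def cap(y1: float, y2: float, x0: float, direction: float, n: int = 7):
        mid = 0.5 * (y1 + y2)
        r = 0.5 * abs(y2 - y1)
        pts = []
        for k in range(1, n):
            th = math.pi * k / n
            pts.append((x0 + direction * r * math.sin(th),
                        mid - r * math.cos(th), 0.0))
        return pts  # runs from near y1 to near y2

    # assemble a single closed loop: walk wires, hop caps between levels
    # (wire i starts at level i; end_wire maps final level -> wire index)
    end_wire = {int(round(paths[i][-1][1])): i for i in range(4)}
    partner = {0: 1, 1: 0, 2: 3, 3: 2}
    curve: list[tuple[float, float, float]] = []
    used: set[int] = set()
    wire, forward = 0, True
    for _ in range(8):
        used.add(wire)
        pts = paths[wire] if forward else paths[wire][::-1]
        curve.extend(pts)
        at_end = forward  # forward traversal arrives at the x_end boundary
        lv = int(round(pts[-1][1]))
        pl = partner[lv]
        curve.extend(
            cap(float(lv), float(pl), x_end if at_end else 0.0,
                1.0 if at_end else -1.0)
        )
        next_wire = end_wire[pl] if at_end else pl
        next_forward = not at_end
        if next_wire == 0 and next_forward:
            break
        wire, forward = next_wire, next_forward
    else:
        raise RuntimeError("4-plat closure walk did not terminate")
    if len(used) != 4:
        raise RuntimeError("4-plat closure left unused strands (link?)")

    verts = np.array(curve, dtype=float)
    # drop consecutive duplicates
    keep = [0]
    for i in range(1, len(verts)):
        if np.linalg.norm(verts[i] - verts[keep[-1]]) > 1e-9:
            keep.append(i)
    if np.linalg.norm(verts[keep[-1]] - verts[keep[0]]) < 1e-9:
        keep.pop()
    verts = verts[keep]
    rng = np.random.default_rng(jitter_seed)
    verts = verts + rng.normal(scale=1e-4, size=verts.shape)
    return FixtureCurve(
        verts, name, "undetermined", 0,
        {"quotients": list(quotients), "determinant": p},
    )


def twist_knot_curve(n_crossings: int, jitter_seed: int = 7) -> FixtureCurve:
    """Twist knot with the given crossing number (3_1, 4_1, 5_2, 6_1, ...)."""
    if n_crossings < 3:
        raise ValueError("twist knots start at 3 crossings")
    name = {3: "3_1", 4: "4_1", 5: "5_2", 6: "6_1", 7: "7_2",
            8: "8_1", 9: "9_2"}.get(n_crossings)
    quotients = [n_crossings - 2, 2]
    fix = rational_knot_curve(quotients, jitter_seed)
    return FixtureCurve(
        fix.vertices, name or f"twist_{n_crossings}", "undetermined", 0,
        dict(fix.params),
    )


def random_ring(n_edges: int, seed: int = 0, tol: float = 1e-9) -> FixtureCurve:
    """Closed equilateral random polygon with unit edges (seeded).

    Random unit steps are alternately recentred (to close the loop) and
    renormalised (to restore unit length) until both hold to ``tol``.
    """
    if n_edges < 3:
        raise ValueError("need at least 3 edges")
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_edges, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    for _ in range(10_000):
        steps = steps - steps.mean(axis=0)
        norms = np.linalg.norm(steps, axis=1, keepdims=True)
        steps = steps / norms
        if np.linalg.norm(steps.sum(axis=0)) < tol:
            break
    else:
        raise RuntimeError("random ring closure did not converge")
    verts = np.concatenate([[np.zeros(3)], np.cumsum(steps, axis=0)[:-1]])
    return FixtureCurve(verts, "random_ring", "undetermined", 0,
                        {"n_edges": n_edges, "seed": seed})


def hairpin_chain(N: int, fold_at: int) -> np.ndarray:
    """Open chain running +x then folded once back at ``fold_at``.

    Returns an (N, 3) array; the x-index projection has exactly one sign
    change and the span is max(fold_at, N - fold_at) - 1.
    """
    if not (1 < fold_at < N):
        raise ValueError("fold_at must be strictly inside the chain")
    pos = np.zeros((N, 3))
    pos[:fold_at, 0] = np.arange(1, fold_at + 1, dtype=float)
    n2 = N - fold_at
    pos[fold_at:, 0] = fold_at - np.arange(0, n2, dtype=float)
    pos[fold_at:, 1] = 1.0
    return pos
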