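"""Jones polynomial via the Kauffman bracket state sum.

The bracket of a diagram D with c crossings is

    <D> = sum over the 2^c smoothing states of  A^(a-b) * d^(|loops|-1),
    d = -A^2 - A^(-2),

where a and b count A- and B-smoothings.  The Jones polynomial follows by
writhe normalisation and substitution:

    V(t) = (-A)^(-3w) <D>,   A = t^(-1/4).

Two independent evaluation paths are provided: a flat numba state sum used
in production, and a small recursive skein expansion used as an oracle in
the tests.  Both consume the same smoothing-pairing table derived from the
diagram's planar geometry: at a crossing of sign s, the A-smoothing joins
(over-out, under-in) and (under-out, over-in) when s = +1, and
(over-out, under-out), (over-in, under-in) when s = -1.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .diagram import KnotDiagram
from .laurent import LaurentPoly

__all__ = [
    "DiagramTooComplexError",
    "jones_polynomial",
    "kauffman_bracket",
    "kauffman_bracket_recursive",
]


class DiagramTooComplexError(RuntimeError):
    """Crossing count exceeds the state-sum cap (caller maps this to '?')."""


def _smoothing_pairs(diagram: KnotDiagram):
    """Per crossing, the arc pairs joined by the A- and B-smoothing.

    Arcs are the curve pieces between consecutive passages: arc p runs from
    passage p to passage p+1 (cyclically), so passage p has in-arc p-1 and
    out-arc p.
    """
    n = len(diagram.passages)
    pos: dict[int, dict[bool, int]] = {}
    for p, (label, over) in enumerate(diagram.passages):
        pos.setdefault(label, {})[over] = p
    signs = diagram.signs
    a_pairs = np.zeros((n // 2, 2, 2), dtype=np.int64)
    b_pairs = np.zeros((n // 2, 2, 2), dtype=np.int64)
    for k, label in enumerate(sorted(pos)):
        po = pos[label][True]
        pu = pos[label][False]
        oi, oo = (po - 1) % n, po
        ui, uo = (pu - 1) % n, pu
        if signs[label] > 0:
            a1, a2 = (oo, ui), (uo, oi)
            b1, b2 = (oo, uo), (oi, ui)
        else:
            a1, a2 = (oo, uo), (oi, ui)
            b1, b2 = (oo, ui), (uo, oi)
        a_pairs[k, 0] = a1
        a_pairs[k, 1] = a2
        b_pairs[k, 0] = b1
        b_pairs[k, 1] = b2
    return a_pairs, b_pairs


@njit(cache=True)
def _find(parent, x):
    while parent[x] != x:
        parent[x] = parent[parent[x]]
        x = parent[x]
    return x


@njit(cache=True)
def _bracket_state_sum(a_pairs, b_pairs, n_arcs):
    """Bracket coefficients over A-exponents; returns (coeffs, offset)."""
    c = a_pairs.shape[0]
    max_loops = c + 2
    binom = np.zeros((max_loops + 1, max_loops + 1), dtype=np.int64)
    for i in range(max_loops + 1):
        binom[i, 0] = 1
        for j in range(1, i + 1):
            binom[i, j] = binom[i - 1, j - 1] + binom[i - 1, j]
    offset = 3 * c + 2 * max_loops + 4
    coeffs = np.zeros(2 * offset + 1, dtype=np.int64)
    parent = np.empty(n_arcs, dtype=np.int64)
    for state in range(1 << c):
        for i in range(n_arcs):
            parent[i] = i
        a_count = 0
        for k in range(c):
            if (state >> k) & 1:
                a_count += 1
                pairs = a_pairs[k]
            else:
                pairs = b_pairs[k]
            for m in range(2):
                ra = _find(parent, pairs[m, 0])
                rb = _find(parent, pairs[m, 1])
                if ra != rb:
                    parent[ra] = rb
        loops = 0
        for i in range(n_arcs):
            if _find(parent, i) == i:
                loops += 1
        e0 = 2 * a_count - c  # a - b
        ell = loops - 1
        sign = -1 if (ell % 2 == 1) else 1
        for m in range(ell + 1):
            e = e0 + 2 * ell - 4 * m
            coeffs[e + offset] += sign * binom[ell, m]
    return coeffs, offset


def kauffman_bracket(diagram: KnotDiagram) -> LaurentPoly:
    """Bracket polynomial in A (quarter-exponent keys store A-powers x4? no:
    keys hold the A exponent directly; see :func:`jones_polynomial`)."""
    if diagram.n_crossings == 0:
        return LaurentPoly.one()
    a_pairs, b_pairs = _smoothing_pairs(diagram)
    coeffs, offset = _bracket_state_sum(
        a_pairs, b_pairs, len(diagram.passages)
    )
    d: dict[int, int] = {}
    for idx in np.nonzero(coeffs)[0]:
        d[int(idx) - offset] = int(coeffs[idx])
    return LaurentPoly.from_dict(d)


def _recursive_bracket(a_pairs, b_pairs, n_arcs) -> dict[int, int]:
    """Skein-triple recursion: resolve crossings one at a time (oracle)."""
    c = a_pairs.shape[0]
    out: dict[int, int] = {}

    def loops_of(unions) -> int:
        parent = list(range(n_arcs))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for x, y in unions:
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[rx] = ry
        return sum(1 for i in range(n_arcs) if find(i) == i)

    def recurse(k, unions, a_count):
        if k == c:
            ell = loops_of(unions) - 1
            e0 = 2 * a_count - c
            sign = -1 if ell % 2 else 1
            from math import comb

            for m in range(ell + 1):
                e = e0 + 2 * ell - 4 * m
                out[e] = out.get(e, 0) + sign * comb(ell, m)
            return
        pa = [tuple(a_pairs[k, 0]), tuple(a_pairs[k, 1])]
        pb = [tuple(b_pairs[k, 0]), tuple(b_pairs[k, 1])]
        recurse(k + 1, unions + pa, a_count + 1)
        recurse(k + 1, unions + pb, a_count)

    recurse(0, [], 0)
    return {e: v for e, v in out.items() if v != 0}


def kauffman_bracket_recursive(diagram: KnotDiagram) -> LaurentPoly:
    """Independent second evaluation path for the bracket (test oracle)."""
    if diagram.n_crossings == 0:
        return LaurentPoly.one()
    a_pairs, b_pairs = _smoothing_pairs(diagram)
    return LaurentPoly.from_dict(
        _recursive_bracket(a_pairs, b_pairs, len(diagram.passages))
    )


def jones_polynomial(
    diagram: KnotDiagram,
    max_crossings: int = 22,
    _bracket=kauffman_bracket,
) -> LaurentPoly:
    """V(t) of the knot represented by ``diagram``.

    Exponent keys of the result are in units of t^(1/4); for knots every
    key is a multiple of 4 (integer powers of t).  Raises
    :class:`DiagramTooComplexError` above ``max_crossings``.
    """
    if diagram.n_crossings > max_crossings:
        raise DiagramTooComplexError(
            f"{diagram.n_crossings} crossings exceeds cap {max_crossings}"
        )
    bracket = _bracket(diagram)
    w = diagram.writhe
    # (-A)^(-3w) <D>, then A = t^(-1/4): A-exponent e -> quarter-exponent -e
    sign = -1 if (w % 2) else 1
    d: dict[int, int] = {}
    for e, coeff in bracket.coeffs:
        d[-(e - 3 * w)] = sign * coeff
    return LaurentPoly.from_dict(d)
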