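"""Planar knot diagrams: projection of 3D curves and Reidemeister reduction.

A diagram is stored as the cyclic sequence of crossing *passages* met while
traversing the curve (each crossing appears exactly twice, once over and
once under) plus, per crossing, the orientation of the first-met strand
relative to the second (``cross12``), from which the right-hand-rule
crossing sign follows:

    sign = cross12   when the first passage is the over strand,
         = -cross12  otherwise.

Projections are taken along a viewing direction; near-degenerate events
(parallel segments, grazing intersections, depth ties) trigger a seeded
redraw of the direction so every produced diagram is generic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KnotDiagram",
    "ProjectionError",
    "project_to_diagram",
    "simplify_diagram",
    "make_alternating",
]

_EPS = 1e-9


class ProjectionError(RuntimeError):
    """No generic projection found within the attempt budget."""


@dataclass(frozen=True)
class KnotDiagram:
    """Crossing code of a closed curve under one planar projection."""

    passages: tuple[tuple[int, bool], ...]   # (crossing label, is_over)
    cross12: dict[int, int] = field(default_factory=dict)
    projection: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        counts: dict[int, list[bool]] = {}
        for label, over in self.passages:
            counts.setdefault(label, []).append(over)
        for label, overs in counts.items():
            if len(overs) != 2 or overs[0] == overs[1]:
                raise ValueError(
                    f"crossing {label} must appear exactly once over and "
                    f"once under"
                )
            if label not in self.cross12:
                raise ValueError(f"missing cross12 entry for crossing {label}")
            if self.cross12[label] not in (-1, 1):
                raise ValueError("cross12 entries must be -1 or +1")

    @property
    def n_crossings(self) -> int:
        return len(self.passages) // 2

    @property
    def signs(self) -> dict[int, int]:
        """Right-hand-rule sign of each crossing."""
        first_over: dict[int, bool] = {}
        for label, over in self.passages:
            if label not in first_over:
                first_over[label] = over
        return {
            label: (c12 if first_over[label] else -c12)
            for label, c12 in self.cross12.items()
        }

    @property
    def writhe(self) -> int:
        return sum(self.signs.values())

    @property
    def gauss_code(self) -> tuple[int, ...]:
        """Signed Gauss code: +label for over passages, -label for under
        (labels renumbered from 1 in order of first appearance)."""
        renum: dict[int, int] = {}
        out = []
        for label, over in self.passages:
            if label not in renum:
                renum[label] = len(renum) + 1
            out.append(renum[label] if over else -renum[label])
        return tuple(out)

    def mirror(self) -> "KnotDiagram":
        """Flip every crossing (over <-> under); negates every sign."""
        return KnotDiagram(
            tuple((label, not over) for label, over in self.passages),
            dict(self.cross12),
            self.projection,
        )


def _make_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _find_crossings(uv: np.ndarray, depth: np.ndarray):
    """All transverse self-intersections of the closed 2D polyline.

    Returns a list of events (i, si, j, sj, over_first, cross12) or None
    when the projection is degenerate.  i < j are segment indices; si, sj
    the intersection fractions; over_first says whether the passage on
    segment i is the over strand.
    """
    m = uv.shape[0]
    starts = uv
    vecs = np.roll(uv, -1, axis=0) - uv
    seg_len = np.linalg.norm(vecs, axis=1)
    scale = float(seg_len.max()) + 1e-30
    margin = 1e-9 * scale  # spatial tolerance for vertex-grazing events
    events = []
    for i in range(m - 2):
        j0 = i + 2
        j_hi = m if i > 0 else m - 1  # segment 0 is adjacent to the last
        js = np.arange(j0, j_hi)
        if len(js) == 0:
            continue
        r = vecs[i]
        li = seg_len[i]
        q = starts[js]
        w = vecs[js]
        lj = seg_len[js]
        denom = r[0] * w[:, 1] - r[1] * w[:, 0]
        dq = q - starts[i]
        s_num = dq[:, 0] * w[:, 1] - dq[:, 1] * w[:, 0]
        u_num = dq[:, 0] * r[1] - dq[:, 1] * r[0]
        parallel = np.abs(denom) <= 1e-12 * li * lj
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(parallel, np.nan, s_num / denom)
            u = np.where(parallel, np.nan, u_num / denom)
        if np.any(parallel):
            # parallel pairs are degenerate only when their supporting
            # lines coincide and the projected ranges overlap
            for idx in np.nonzero(parallel)[0]:
                d0 = dq[idx]
                offset = abs(d0[0] * r[1] - d0[1] * r[0]) / (li + 1e-30)
                if offset > margin:
                    continue
                t1 = (d0 @ r) / (li * li + 1e-30)
                t2 = t1 + (w[idx] @ r) / (li * li + 1e-30)
                lo, hi = min(t1, t2), max(t1, t2)
                if hi > 1e-9 and lo < 1.0 - 1e-9:
                    return None  # collinear overlap
            continue_mask = ~parallel
        else:
            continue_mask = np.ones(len(js), dtype=bool)
        # spatial distance of the line-line crossing point from the
        # nearest vertex of each segment
        with np.errstate(invalid="ignore"):
            m_i = np.minimum(s, 1.0 - s) * li
            m_j = np.minimum(u, 1.0 - u) * lj
        ok = continue_mask & (m_i > margin) & (m_j > margin)
        grazing = continue_mask & ~ok & (m_i > -margin) & (m_j > -margin)
        if np.any(grazing):
            return None
        for idx in np.nonzero(ok)[0]:
            j = int(js[idx])
            si, sj = float(s[idx]), float(u[idx])
            di = depth[i] + si * (depth[(i + 1) % m] - depth[i])
            dj = depth[j] + sj * (depth[(j + 1) % m] - depth[j])
            if abs(di - dj) < 1e-9:
                return None
            ti = r / li
            tj = w[idx] / lj[idx]
            cr = ti[0] * tj[1] - ti[1] * tj[0]
            if abs(cr) < 1e-12:
                return None
            events.append((i, si, j, sj, di > dj, 1 if cr > 0 else -1))
    return events


def project_to_diagram(
    vertices: np.ndarray,
    direction: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = 50,
) -> KnotDiagram:
    """Generic planar projection of a closed polygonal curve.

    ``vertices`` holds the closed curve without a duplicated endpoint.
    The first attempt uses ``direction`` when given; degenerate projections
    redraw a uniform random direction from ``rng`` (seeded by the caller).
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3:
        raise ValueError("need a closed curve with at least 3 vertices")
    rng = rng if rng is not None else np.random.default_rng(0)
    for attempt in range(max_attempts):
        if attempt == 0 and direction is not None:
            d = np.asarray(direction, dtype=float)
        else:
            d = rng.normal(size=3)
        d = d / np.linalg.norm(d)
        e1, e2 = _make_basis(d)
        uv = np.column_stack([verts @ e1, verts @ e2])
        depth = verts @ d
        events = _find_crossings(uv, depth)
        if events is None:
            continue
        # order passages along the traversal
        passages_raw = []
        for label, (i, si, j, sj, over_first, c12) in enumerate(events):
            passages_raw.append(((i, si), label, over_first))
            passages_raw.append(((j, sj), label, not over_first))
        passages_raw.sort(key=lambda e: e[0])
        keys = [k for k, _, _ in passages_raw]
        if any(
            keys[a][0] == keys[a + 1][0]
            and abs(keys[a][1] - keys[a + 1][1]) < 1e-12
            for a in range(len(keys) - 1)
        ):
            continue
        # cross12 is defined in *passage* order (first met strand first);
        # events store tangent cross of segment i vs segment j
        passages = []
        cross12: dict[int, int] = {}
        seen: set[int] = set()
        for (seg, frac), label, _ in passages_raw:
            i, si, j, sj, over_first, c12 = events[label]
            on_i = seg == i and abs(frac - si) < 1e-15
            if label not in seen:
                seen.add(label)
                cross12[label] = c12 if on_i else -c12
            passages.append((label, over_first if on_i else not over_first))
        return KnotDiagram(tuple(passages), cross12, tuple(d))
    raise ProjectionError(
        f"no generic projection found in {max_attempts} attempts"
    )


def _r1_positions(passages) -> int | None:
    n = len(passages)
    for p in range(n):
        if passages[p][0] == passages[(p + 1) % n][0]:
            return p
    return None


def _r2_positions(passages):
    n = len(passages)
    adj: dict[frozenset, list[int]] = {}
    for p in range(n):
        a, oa = passages[p]
        b, ob = passages[(p + 1) % n]
        if a != b and oa == ob:
            adj.setdefault(frozenset((a, b)), []).append(p)
    for pair, positions in adj.items():
        if len(positions) >= 2:
            p, q = positions[0], positions[1]
            # the two adjacent pairs must be disjoint occurrences
            used = {p, (p + 1) % n, q, (q + 1) % n}
            if len(used) == 4:
                return p, q
    return None


def simplify_diagram(diagram: KnotDiagram) -> KnotDiagram:
    """Repeated Reidemeister I and II reduction to a fixpoint.

    Preserves the knot type and never increases the crossing count; the
    Jones polynomial of the output equals that of the input.
    """
    passages = list(diagram.passages)
    cross12 = dict(diagram.cross12)
    changed = True
    while changed:
        changed = False
        p = _r1_positions(passages)
        if p is not None:
            n = len(passages)
            label = passages[p][0]
            drop = {p, (p + 1) % n}
            passages = [x for k, x in enumerate(passages) if k not in drop]
            cross12.pop(label, None)
            changed = True
            continue
        r2 = _r2_positions(passages)
        if r2 is not None:
            p, q = r2
            n = len(passages)
            labels = {passages[p][0], passages[(p + 1) % n][0]}
            drop = {p, (p + 1) % n, q, (q + 1) % n}
            passages = [x for k, x in enumerate(passages) if k not in drop]
            for lab in labels:
                cross12.pop(lab, None)
            changed = True
    return KnotDiagram(tuple(passages), cross12, diagram.projection)


def make_alternating(diagram: KnotDiagram) -> KnotDiagram:
    """Reassign over/under so passages alternate along the traversal.

    Only possible when each crossing's two passages sit at positions of
    opposite parity (true for standard rational-knot plat diagrams); used
    by the bundled-table builder to canonicalise generated diagrams.
    """
    pos: dict[int, list[int]] = {}
    for p, (label, _) in enumerate(diagram.passages):
        pos.setdefault(label, []).append(p)
    for label, (p1, p2) in pos.items():
        if (p1 - p2) % 2 == 0:
            raise ValueError(
                "diagram does not admit an alternating over/under assignment"
            )
    passages = tuple(
        (label, p % 2 == 0) for p, (label, _) in enumerate(diagram.passages)
    )
    return KnotDiagram(passages, dict(diagram.cross12), diagram.projection)
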