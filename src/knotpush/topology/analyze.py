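"""Per-frame topology analysis and ensemble knotting statistics.

For every sampled frame the chain writhe is computed (open curve, Gauss
integral as-is); knot typing runs only on frames passing the ligation
filter.  Typing projects the closed curve along several seeded directions,
keeps the Reidemeister-reduced diagram with the fewest crossings, evaluates
the Jones polynomial (diagrams above the crossing cap become the
unidentified "?" bucket) and matches it against the bundled table.

Equichiral knots are identified knots whose handedness equals the channel
winding sign; antichiral ones oppose it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..channel import ChannelSpec
from ..dynamics import Trajectory
from .closure import ClosureError, close_chain
from .diagram import KnotDiagram, ProjectionError, project_to_diagram, simplify_diagram
from .jones import jones_polynomial
from .laurent import LaurentPoly
from .tables import (
    UNIDENTIFIED,
    UNKNOT,
    KnotTables,
    classify_groups,
    crossing_number_of,
    handedness,
    identify_knot,
    load_tables,
)
from .writhe import gauss_writhe

__all__ = [
    "TopologyResult",
    "KnotStats",
    "identify_curve",
    "best_diagram",
    "analyze_trajectory",
    "compute_stats",
]


@dataclass(frozen=True)
class TopologyResult:
    """Topology of one frame."""

    frame_index: int
    writhe: float
    end_to_end: float
    ligation_accepted: bool
    name: Optional[str] = None          # None when not typed
    mirror: Optional[bool] = None
    handedness: str = "undetermined"
    min_crossing_bound: Optional[int] = None
    closure_failed: bool = False

    @property
    def typed(self) -> bool:
        return self.name is not None

    @property
    def knotted(self) -> Optional[bool]:
        if not self.typed:
            return None
        return self.name != UNKNOT


@dataclass
class KnotStats:
    """Ensemble summary; all denominators are reported explicitly."""

    n_frames: int = 0
    n_ligation_accepted: int = 0
    n_typed: int = 0
    n_closure_failures: int = 0
    n_knotted: int = 0
    knotting_probability: float = float("nan")
    crossing_number_freq: dict = field(default_factory=dict)
    group_freq: dict = field(default_factory=dict)
    n_equichiral: int = 0
    n_antichiral: int = 0
    equichiral_fraction: float = float("nan")
    mean_writhe: float = float("nan")
    sem_writhe: float = float("nan")


def best_diagram(
    vertices: np.ndarray,
    n_projections: int = 5,
    rng: np.random.Generator | None = None,
) -> KnotDiagram:
    """Smallest Reidemeister-reduced diagram over several projections."""
    rng = rng if rng is not None else np.random.default_rng(0)
    best: KnotDiagram | None = None
    for _ in range(n_projections):
        try:
            d = project_to_diagram(vertices, rng=rng)
        except ProjectionError:
            continue
        ds = simplify_diagram(d)
        if best is None or ds.n_crossings < best.n_crossings:
            best = ds
        if best.n_crossings == 0:
            break
    if best is None:
        raise ProjectionError("all projection attempts failed")
    return best


def identify_curve(
    vertices: np.ndarray,
    tables: KnotTables | None = None,
    n_projections: int = 5,
    max_crossings: int = 22,
    rng: np.random.Generator | None = None,
) -> tuple[str, bool, Optional[LaurentPoly], int]:
    """Knot type of a closed curve.

    Returns (name, mirror, jones or None, crossing lower bound).  Diagrams
    that stay above ``max_crossings`` after reduction give ("?", False,
    None, bound).
    """
    tables = tables or load_tables()
    diagram = best_diagram(vertices, n_projections, rng)
    if diagram.n_crossings > max_crossings:
        return UNIDENTIFIED, False, None, diagram.n_crossings
    poly = jones_polynomial(diagram, max_crossings)
    name, mirror = identify_knot(poly, tables)
    return name, mirror, poly, diagram.n_crossings


def analyze_trajectory(
    trajectory: Trajectory,
    channel: ChannelSpec | None = None,
    tables: KnotTables | None = None,
    ligation_distance: float = 10.0,
    max_crossings: int = 22,
    n_projections: int = 5,
    seed: int = 0,
    frame_stride: int = 1,
) -> tuple[list[TopologyResult], KnotStats]:
    """Topology of every ``frame_stride``-th frame plus ensemble statistics."""
    tables = tables or load_tables()
    channel = channel if channel is not None else trajectory.channel
    rng = np.random.default_rng(seed)
    results: list[TopologyResult] = []
    for idx in range(0, trajectory.n_frames, frame_stride):
        chain = trajectory.chain_frames[idx]
        wr = gauss_writhe(chain, closed=False)
        e2e = float(np.linalg.norm(chain[-1] - chain[0]))
        try:
            closed = close_chain(
                chain, ligation_distance, provenance=f"frame {idx}"
            )
        except ClosureError:
            results.append(
                TopologyResult(idx, wr, e2e, True, closure_failed=True)
            )
            continue
        if closed is None:
            results.append(TopologyResult(idx, wr, e2e, False))
            continue
        try:
            name, mirror, poly, bound = identify_curve(
                closed.vertices, tables, n_projections, max_crossings, rng
            )
        except ProjectionError:
            results.append(
                TopologyResult(idx, wr, e2e, True, closure_failed=True)
            )
            continue
        hand = handedness(name, mirror, tables) if name != UNIDENTIFIED \
            else "undetermined"
        results.append(
            TopologyResult(
                idx, wr, e2e, True, name, mirror, hand, bound
            )
        )
    stats = compute_stats(results, channel)
    return results, stats


def compute_stats(
    results: Sequence[TopologyResult],
    channel: ChannelSpec | None = None,
    tables: KnotTables | None = None,
) -> KnotStats:
    """Aggregate per-frame results into ensemble statistics."""
    tables = tables or load_tables()
    stats = KnotStats(n_frames=len(results))
    writhes = [r.writhe for r in results]
    if writhes:
        stats.mean_writhe = float(np.mean(writhes))
        stats.sem_writhe = float(
            np.std(writhes, ddof=1) / np.sqrt(len(writhes))
        ) if len(writhes) > 1 else float("nan")
    typed = [r for r in results if r.typed]
    stats.n_ligation_accepted = sum(
        1 for r in results if r.ligation_accepted
    )
    stats.n_closure_failures = sum(1 for r in results if r.closure_failed)
    stats.n_typed = len(typed)
    if typed:
        stats.n_knotted = sum(1 for r in typed if r.name != UNKNOT)
        stats.knotting_probability = stats.n_knotted / len(typed)
        spectrum: dict = {}
        groups = {"amphichiral": 0, "torus": 0, "twist": 0, "unknot": 0,
                  "unidentified": 0}
        for r in typed:
            if r.name == UNIDENTIFIED:
                key = "unidentified"
                groups["unidentified"] += 1
            else:
                cn = crossing_number_of(r.name, tables)
                key = cn if cn is not None else "unidentified"
                if r.name == UNKNOT:
                    groups["unknot"] += 1
                else:
                    for g in classify_groups(r.name, tables):
                        groups[g] += 1
            spectrum[key] = spectrum.get(key, 0) + 1
        stats.crossing_number_freq = {
            k: v / len(typed) for k, v in sorted(
                spectrum.items(), key=lambda kv: str(kv[0])
            )
        }
        stats.group_freq = {k: v / len(typed) for k, v in groups.items()}
    if channel is not None and not channel.is_cylinder:
        want = "right" if channel.handedness > 0 else "left"
        opposite = "left" if channel.handedness > 0 else "right"
        stats.n_equichiral = sum(
            1 for r in typed if r.handedness == want
        )
        stats.n_antichiral = sum(
            1 for r in typed if r.handedness == opposite
        )
        total = stats.n_equichiral + stats.n_antichiral
        if total:
            stats.equichiral_fraction = stats.n_equichiral / total
    return stats
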