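"""Polymer metrics and monomer-distribution analyses.

The primary compaction observable is the *span*: the largest separation of
two monomers along the channel axis (the x coordinate), which is less
sensitive to chain-end effects than the full 3D extent.  Distribution
analyses (radial, axial from the piston face, helical-turn-periodized
heatmaps, index-position projections) summarise where monomers sit inside
the channel; the compression-scaling fit extracts the exponent of the
force-diameter-span relation F*D ~ S^(-9/4) from steady-state spans.
"""

from __future__ import annotations

import numpy as np

from .channel import ChannelSpec
from .dynamics import Trajectory

__all__ = [
    "span",
    "chain_size",
    "steady_state_span",
    "radial_distribution",
    "axial_distribution",
    "periodized_heatmap",
    "index_position_projection",
    "persistence_length",
    "fit_compression_scaling",
]


def span(frame: np.ndarray) -> float:
    """Axial span max_i(x_i) - min_i(x_i) of one chain frame (piston excluded)."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    x = frame[:, 0] if frame.ndim == 2 else frame
    return float(x.max() - x.min())


def chain_size(frame: np.ndarray) -> tuple[float, float]:
    """End-to-end distance and gyration radius of one chain frame."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape[0] < 2:
        raise ValueError("need at least two beads")
    e2e = float(np.linalg.norm(frame[-1] - frame[0]))
    com = frame.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum((frame - com) ** 2, axis=1))))
    return e2e, rg


def steady_state_span(trajectory: Trajectory, fraction: float = 0.5) -> float:
    """Mean span over the last ``fraction`` of production frames."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    frames = trajectory.chain_frames
    start = int(round((1.0 - fraction) * len(frames)))
    return float(np.mean([span(f) for f in frames[start:]]))


def radial_distribution(
    trajectory: Trajectory, channel: ChannelSpec, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized frequency of bead distances from the channel axis.

    Frequency per bin (not an annulus-corrected density), binned over
    [0, R_ch + R_H] — a helical tube reaches that far from its symmetry
    axis.  Raises if any bead lies beyond that bound (escaped bead).
    """
    r = np.sqrt(
        trajectory.chain_frames[:, :, 1] ** 2
        + trajectory.chain_frames[:, :, 2] ** 2
    ).ravel()
    r_max = channel.R_ch + channel.R_H
    if np.any(r > r_max):
        raise ValueError("bead found outside the channel radius")
    counts, edges = np.histogram(r, bins=n_bins, range=(0.0, r_max))
    freq = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, freq


def axial_distribution(
    trajectory: Trajectory, n_bins: int = 100,
    range_sigma: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of bead offsets from the piston face along the push.

    The piston face is the origin; the push goes toward decreasing x, so a
    bead ahead of the piston (smaller x) has positive offset and a bead
    behind the face (not yet contacted) has negative offset.  Returns
    (bin centers, counts); total counts equal beads x frames when no range
    is given.
    """
    if not trajectory.has_piston:
        raise ValueError("axial distribution requires a piston trajectory")
    face = (
        trajectory.piston_x_series[:, None]
        - trajectory.piston.contact_sigma
        + 0.5
    )
    s = (face - trajectory.chain_frames[:, :, 0]).ravel()
    if range_sigma is None:
        range_sigma = (float(s.min()), float(s.max()) + 1e-9)
    counts, edges = np.histogram(s, bins=n_bins, range=range_sigma)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def periodized_heatmap(
    trajectory: Trajectory,
    channel: ChannelSpec,
    n_bins_axial: int = 40,
    n_bins_transverse: int = 40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D monomer counts over one helical turn, in the co-rotating frame.

    The axial coordinate is x mod d_H; the transverse coordinate is the
    bead's distance from the axis, signed by the sign of its y coordinate
    after rotating the frame by ``-handedness * x/k`` about x.  In that
    unwound frame the helix centerline is stationary at +R_H, so beads
    following the groove trace a horizontal hot line.  For a cylinder the
    period falls back to the channel diameter.  Returns (axial edges,
    transverse edges, counts); counts sum to beads x frames.
    """
    period = channel.d_H if not channel.is_cylinder else channel.D
    pos = trajectory.chain_frames.reshape(-1, 3)
    x = pos[:, 0]
    if channel.is_cylinder:
        phase = np.zeros_like(x)
    else:
        phase = -channel.handedness * x / channel.k
    c, s = np.cos(phase), np.sin(phase)
    y_rot = c * pos[:, 1] - s * pos[:, 2]
    r = np.sqrt(pos[:, 1] ** 2 + pos[:, 2] ** 2)
    transverse = np.sign(y_rot) * r
    x_mod = np.mod(x, period)
    counts, xe, te = np.histogram2d(
        x_mod,
        transverse,
        bins=(n_bins_axial, n_bins_transverse),
        range=((0.0, period), (-channel.R_ch, channel.R_ch)),
    )
    return xe, te, counts


def index_position_projection(frame: np.ndarray) -> np.ndarray:
    """(bead index, x) pairs; backfolded conformations are non-monotone."""
    frame = np.asarray(frame, dtype=float)
    idx = np.arange(frame.shape[0])
    return np.column_stack([idx, frame[:, 0]])


def persistence_length(
    trajectory: Trajectory, max_lag: int = 6
) -> float:
    """Persistence length from bond-direction correlations, in sigma.

    Fits ln<u_i . u_(i+s)> = -s*l/P over lags 1..max_lag.  The default
    window is short (about P/3 for the default force field) because the
    long-lag correlations of a self-avoiding chain decay slower than
    exponentially and would bias P upward.
    """
    frames = trajectory.chain_frames
    bonds = frames[:, 1:, :] - frames[:, :-1, :]
    norm = np.linalg.norm(bonds, axis=2, keepdims=True)
    u = bonds / norm
    n_bonds = u.shape[1]
    if max_lag >= n_bonds:
        raise ValueError("max_lag must be smaller than the number of bonds")
    lags = np.arange(1, max_lag + 1)
    corr = np.array(
        [
            float(np.einsum("fid,fid->fi", u[:, :-s_, :], u[:, s_:, :]).mean())
            for s_ in lags
        ]
    )
    if np.any(corr <= 0):
        raise ValueError(
            "non-positive bond correlation in the fit window; "
            "chain too flexible for an exponential fit"
        )
    slope = np.polyfit(lags, np.log(corr), 1)[0]
    if slope >= 0:
        raise ValueError("non-decaying bond correlation; fit failed")
    return float(-1.0 / slope)


def fit_compression_scaling(
    spans: np.ndarray, forces: np.ndarray, D: float
) -> float:
    """Least-squares slope of log(F*D) against log(S).

    For pushed chains in the de Gennes compression regime the expected
    slope is -9/4 (F*D proportional to S^(-9/4)).
    """
    spans = np.asarray(spans, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if spans.shape != forces.shape or spans.size < 2:
        raise ValueError("need matching spans and forces, at least two pairs")
    if np.any(spans <= 0) or np.any(forces <= 0) or D <= 0:
        raise ValueError("spans, forces and D must be positive")
    slope = np.polyfit(np.log(spans), np.log(forces * D), 1)[0]
    return float(slope)
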