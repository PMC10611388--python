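"""Implicit helical / cylindrical channel geometry.

The channel is a tube of radius ``R_ch`` around a helical centerline

    r0(t) = (k*t, R_H*cos(w*t), R_H*sin(w*t)),      w = handedness = +-1,

so one helical turn advances the axial coordinate by ``d_H = 2*pi*k``.
``R_H = 0`` degenerates to a straight cylinder around the x axis, whatever
``k`` and the handedness.  Negative handedness winds left, positive right.

Beads never see an explicit wall: the confinement is a purely repulsive
(WCA-form) potential of the *gap* between the bead and the tube surface,
which requires the distance from a point to the helix.  That distance has no
closed form; it is found by multi-start safeguarded Newton refinement of the
stationarity condition, which is cheap and robust because the squared
distance is locally unimodal in ``t`` on half-turn windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelSpec",
    "HelixFootpoint",
    "EscapedBeadError",
    "build_channel",
    "helix_point",
    "distance_to_helix",
    "wall_potential_force",
    "deflection_length",
]

_WCA_CUT = 2.0 ** (1.0 / 6.0)


class EscapedBeadError(RuntimeError):
    """A bead was found at or beyond the channel wall (gap <= 0)."""


@dataclass(frozen=True)
class ChannelSpec:
    """Geometry of one infinite channel, in reduced sigma units.

    Attributes
    ----------
    handedness : int
        Winding sign of the helix: -1 left-handed, +1 right-handed.
        Irrelevant when ``R_H == 0``.
    R_ch : float
        Tube radius.
    R_H : float
        Helix radius of the centerline; 0 gives a straight cylinder.
    k : float
        Pitch parameter; one turn spans ``d_H = 2*pi*k`` along x.
    """

    handedness: int = 1
    R_ch: float = 10.0
    R_H: float = 0.0
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.handedness not in (-1, 1):
            raise ValueError(f"handedness must be -1 or +1, got {self.handedness}")
        if self.R_ch <= 0:
            raise ValueError(f"R_ch must be positive, got {self.R_ch}")
        if not (0.0 <= self.R_H < self.R_ch):
            raise ValueError(
                f"R_H must satisfy 0 <= R_H < R_ch, got R_H={self.R_H}, "
                f"R_ch={self.R_ch}"
            )
        if self.R_H > 0 and self.k <= 0:
            raise ValueError("k must be positive for a helical channel")

    @property
    def is_cylinder(self) -> bool:
        return self.R_H == 0.0

    @property
    def d_H(self) -> float:
        """Axial length of one helical turn, 2*pi*k."""
        return 2.0 * math.pi * self.k

    @property
    def D(self) -> float:
        """Channel diameter, 2*R_ch."""
        return 2.0 * self.R_ch


@dataclass(frozen=True)
class HelixFootpoint:
    """Nearest centerline point to a query point."""

    t_star: float
    distance: float
    foot: np.ndarray


def build_channel(
    handedness: int = 1,
    D_over_P: float = 1.0,
    P: float = 20.0,
    RH_ratio: float = 1.0 / 3.0,
    pitch_mode: str = "turn_equals_diameter",
    d_H: float | None = None,
) -> ChannelSpec:
    """Construct a channel from confinement strength D/P.

    ``pitch_mode='turn_equals_diameter'`` sets ``k = D/(2*pi)`` so that one
    helical turn spans exactly one channel diameter; ``pitch_mode='explicit'``
    takes the turn length from ``d_H``.  ``RH_ratio=0`` yields a cylinder.
    """
    if D_over_P <= 0 or P <= 0:
        raise ValueError("D_over_P and P must be positive")
    if not (0.0 <= RH_ratio < 1.0):
        raise ValueError(f"RH_ratio must be in [0, 1), got {RH_ratio}")
    D = D_over_P * P
    R_ch = D / 2.0
    R_H = RH_ratio * R_ch
    if pitch_mode == "turn_equals_diameter":
        k = D / (2.0 * math.pi)
    elif pitch_mode == "explicit":
        if d_H is None or d_H <= 0:
            raise ValueError("pitch_mode='explicit' requires positive d_H")
        k = d_H / (2.0 * math.pi)
    else:
        raise ValueError(f"unknown pitch_mode {pitch_mode!r}")
    return ChannelSpec(handedness=handedness, R_ch=R_ch, R_H=R_H, k=k)


def helix_point(channel: ChannelSpec, t: float | np.ndarray) -> np.ndarray:
    """Point(s) on the centerline at helix parameter ``t`` (radians)."""
    t = np.asarray(t, dtype=float)
    w = channel.handedness
    out = np.stack(
        [
            channel.k * t,
            channel.R_H * np.cos(w * t),
            channel.R_H * np.sin(w * t),
        ],
        axis=-1,
    )
    return out


def _dist2_and_derivs(channel: ChannelSpec, p: np.ndarray, t: float):
    """Squared distance from p to the centerline at t, with d/dt and d2/dt2."""
    k, R, w = channel.k, channel.R_H, channel.handedness
    x, y, z = p
    c = math.cos(w * t)
    s = math.sin(w * t)
    dx = x - k * t
    dy = y - R * c
    dz = z - R * s
    f = dx * dx + dy * dy + dz * dz
    # w**2 == 1 collapses the chain rule terms
    fp = -2.0 * k * dx + 2.0 * R * w * (y * s - z * c)
    fpp = 2.0 * k * k + 2.0 * R * (y * c + z * s)
    return f, fp, fpp


def distance_to_helix(
    point: np.ndarray,
    channel: ChannelSpec,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> HelixFootpoint:
    """Globally nearest centerline point, by multi-start safeguarded Newton.

    Initial guesses are placed every half turn within two turns of the
    point's axial position; each is refined by Newton steps bisected back
    into a shrinking bracket.  Raises if no start converges (which would
    indicate a malformed channel, not a hard geometry).
    """
    p = np.asarray(point, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValueError("point must be a finite 3-vector")
    if channel.is_cylinder:
        d = math.hypot(p[1], p[2])
        t_star = p[0] / channel.k if channel.k > 0 else p[0]
        return HelixFootpoint(
            t_star=t_star, distance=d, foot=np.array([p[0], 0.0, 0.0])
        )

    t_center = p[0] / channel.k
    best_t = None
    best_f = math.inf
    for j in range(-4, 5):
        t = t_center + j * math.pi
        lo, hi = t - math.pi, t + math.pi
        converged = False
        for _ in range(max_iter):
            f, fp, fpp = _dist2_and_derivs(channel, p, t)
            if abs(fp) < tol * max(1.0, abs(f)):
                converged = True
                break
            if fp > 0:
                hi = t
            else:
                lo = t
            if fpp > 0:
                t_new = t - fp / fpp
            else:
                t_new = 0.5 * (lo + hi)
            if not (lo < t_new < hi):
                t_new = 0.5 * (lo + hi)
            if abs(t_new - t) < 1e-14 * max(1.0, abs(t)):
                t = t_new
                converged = True
                break
            t = t_new
        if not converged:
            continue
        f, _, _ = _dist2_and_derivs(channel, p, t)
        if f < best_f:
            best_f = f
            best_t = t
    if best_t is None:
        raise RuntimeError(
            f"distance_to_helix failed to converge for point {p.tolist()} "
            f"on channel {channel}"
        )
    foot = helix_point(channel, best_t)
    return HelixFootpoint(t_star=best_t, distance=math.sqrt(best_f), foot=foot)


def wall_potential_force(
    point: np.ndarray,
    channel: ChannelSpec,
    sigma_wall: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Repulsive WCA wall energy and force for one bead.

    The interaction acts on the gap ``g = R_ch - d`` between the bead and
    the tube surface: zero for ``g >= 2^(1/6)*sigma_wall``, steeply repulsive
    as the bead approaches the wall, always pushing the bead back toward the
    centerline footpoint.  Raises :class:`EscapedBeadError` when ``g <= 0``.
    """
    p = np.asarray(point, dtype=float)
    fp = distance_to_helix(p, channel)
    g = channel.R_ch - fp.distance
    if g <= 0.0:
        raise EscapedBeadError(
            f"bead at {p.tolist()} is outside the tube (gap {g:.4g})"
        )
    if g >= _WCA_CUT * sigma_wall:
        return 0.0, np.zeros(3)
    sr6 = (sigma_wall / g) ** 6
    energy = 4.0 * (sr6 * sr6 - sr6) + 1.0
    dU_dg = 4.0 * (-12.0 * sr6 * sr6 + 6.0 * sr6) / g
    if fp.distance > 1e-12:
        radial = (p - fp.foot) / fp.distance  # centerline -> bead
    else:
        radial = np.zeros(3)
    # F = -dU/dg * grad(g); grad(g) = -radial, dU_dg < 0 => force is inward
    force = dU_dg * radial
    return energy, force


def deflection_length(
    channel: ChannelSpec, P: float, form: str = "odijk"
) -> float:
    """Odijk deflection length of a stiff chain in the tube.

    ``form='odijk'`` gives the standard (D^2 * P)^(1/3); ``form='ratio'``
    gives the alternative (D^2 / P)^(1/3) sometimes quoted.
    """
    if P <= 0:
        raise ValueError("persistence length must be positive")
    D = channel.D
    if form == "odijk":
        return (D * D * P) ** (1.0 / 3.0)
    if form == "ratio":
        return (D * D / P) ** (1.0 / 3.0)
    raise ValueError(f"unknown deflection-length form {form!r}")
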