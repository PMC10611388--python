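"""Bonded and nonbonded interactions of the chain and the piston.

These are straightforward numpy implementations returning (energy, forces)
pairs; the Langevin integrator uses equivalent numba kernels in
:mod:`knotpush._core`, and the two are cross-checked in the test suite.

Potentials (reduced units, epsilon_0 = sigma = 1):

* bond stretch     U_S(r)   = K_s * (r - r0)^2          (stiff, K_s = 80,
  chosen to forbid strand passages under compression)
* angle bend       U_b(th)  = (K_b/2) * (th - pi)^2     (half-prefactor
  convention; persistence length ~ K_b * l)
* excluded volume  U_ex(r)  = 4*[(1/r)^12 - (1/r)^6 + 1/4]   for r < 2^(1/6)
  (WCA: purely repulsive, continuous at the cutoff)
* piston           same WCA with contact scale sigma_c = (1 + sigma_P)/2,
  plus the constant external force -F_ext * x_hat on the piston only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import ForceFieldParams

__all__ = [
    "PistonSpec",
    "bond_energy_forces",
    "angle_energy_forces",
    "excluded_volume_energy_forces",
    "piston_energy_forces",
    "total_internal_energy_forces",
]

_WCA_CUT = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class PistonSpec:
    """The pushing piston: a very large bead constrained to the x axis.

    ``sigma_P`` is its diameter parameter (default 100 sigma, much wider
    than any channel used here) and ``F_ext`` the magnitude of the constant
    force applied along -x.
    """

    sigma_P: float = 100.0
    F_ext: float = 1.0
    x_init: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_P <= 0:
            raise ValueError(f"sigma_P must be positive, got {self.sigma_P}")
        if self.F_ext < 0:
            raise ValueError(f"F_ext must be non-negative, got {self.F_ext}")

    @property
    def contact_sigma(self) -> float:
        """Arithmetic-mean contact distance with a unit bead."""
        return 0.5 * (1.0 + self.sigma_P)


def _wca(r2: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """WCA energy and dU/dr / r for squared distances inside the cutoff."""
    s2 = sigma * sigma / r2
    sr6 = s2 ** 3
    energy = 4.0 * (sr6 * sr6 - sr6) + 1.0
    fac = 4.0 * (12.0 * sr6 * sr6 - 6.0 * sr6) / r2  # = -(dU/dr)/r
    return energy, fac


def bond_energy_forces(
    positions: np.ndarray, params: ForceFieldParams | None = None
) -> tuple[float, np.ndarray]:
    """Harmonic bond-stretch energy and per-bead forces."""
    params = params or ForceFieldParams()
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise ValueError("need at least two beads")
    bonds = pos[1:] - pos[:-1]
    r = np.linalg.norm(bonds, axis=1)
    if np.any(r < 1e-12):
        raise FloatingPointError("coincident bonded beads (zero bond length)")
    energy = float(params.K_s * np.sum((r - params.r0) ** 2))
    fac = (2.0 * params.K_s * (r - params.r0) / r)[:, None]
    forces = np.zeros_like(pos)
    forces[:-1] += fac * bonds
    forces[1:] -= fac * bonds
    return energy, forces


def angle_energy_forces(
    positions: np.ndarray, params: ForceFieldParams | None = None
) -> tuple[float, np.ndarray]:
    """Harmonic angle-bend energy (half-prefactor convention) and forces.

    The bending angle at bead i is the angle between the vectors pointing
    from i to its two bonded neighbours; a straight chain has theta = pi.
    """
    params = params or ForceFieldParams()
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 3:
        raise ValueError("need at least three beads")
    forces = np.zeros_like(pos)
    energy = 0.0
    for i in range(1, pos.shape[0] - 1):
        a = pos[i - 1] - pos[i]
        b = pos[i + 1] - pos[i]
        la = np.linalg.norm(a)
        lb = np.linalg.norm(b)
        if la < 1e-12 or lb < 1e-12:
            raise FloatingPointError(f"zero-length segment at angle {i}")
        a = a / la
        b = b / lb
        ct = float(np.clip(a @ b, -1.0, 1.0))
        theta = math.acos(ct)
        energy += 0.5 * params.K_b * (theta - params.theta0) ** 2
        st = math.sqrt(max(1.0 - ct * ct, 0.0))
        if st > 1e-8:
            q = (theta - params.theta0) / st
        else:
            # regular limit of (theta - pi)/sin(theta) at theta -> pi
            q = -1.0 if theta > 1.5 else (theta - params.theta0) / 1e-8
        f1 = params.K_b * q * (b - ct * a) / la
        f3 = params.K_b * q * (a - ct * b) / lb
        forces[i - 1] += f1
        forces[i + 1] += f3
        forces[i] -= f1 + f3
    return float(energy), forces


def excluded_volume_energy_forces(
    positions: np.ndarray, params: ForceFieldParams | None = None
) -> tuple[float, np.ndarray]:
    """WCA excluded volume over all non-bonded bead pairs (all-pairs)."""
    params = params or ForceFieldParams()
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    forces = np.zeros_like(pos)
    energy = 0.0
    min_sep = 2 if params.exclude_bonded else 1
    for i in range(n):
        for j in range(i + min_sep, n):
            d = pos[j] - pos[i]
            r2 = float(d @ d)
            if r2 < _WCA_CUT * _WCA_CUT * params.lj_sigma**2:
                e, fac = _wca(np.array(r2), params.lj_sigma)
                energy += float(e)
                forces[i] -= float(fac) * d
                forces[j] += float(fac) * d
    return energy, forces


def piston_energy_forces(
    positions: np.ndarray,
    piston_x: float,
    piston: PistonSpec,
    include_external: bool = True,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Piston-bead WCA exclusion and the external push.

    Returns (energy, per-bead forces, force on the piston).  The reaction
    on the piston is minus the sum over beads; the external force
    ``-F_ext*x_hat`` is added to the piston only.
    """
    pos = np.asarray(positions, dtype=float)
    sigma_c = piston.contact_sigma
    center = np.array([piston_x, 0.0, 0.0])
    d = pos - center
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 < (0.3 * sigma_c) ** 2):
        raise FloatingPointError("bead inside the piston core")
    forces = np.zeros_like(pos)
    piston_force = np.zeros(3)
    mask = r2 < (_WCA_CUT * sigma_c) ** 2
    energy = 0.0
    if np.any(mask):
        e, fac = _wca(r2[mask], sigma_c)
        energy = float(np.sum(e))
        f = fac[:, None] * d[mask]
        forces[mask] += f
        piston_force -= f.sum(axis=0)
    if include_external:
        piston_force[0] -= piston.F_ext
    return energy, forces, piston_force


def total_internal_energy_forces(
    positions: np.ndarray, params: ForceFieldParams | None = None
) -> tuple[float, np.ndarray]:
    """Sum of bond, angle and excluded-volume terms for chain beads."""
    params = params or ForceFieldParams()
    e1, f1 = bond_energy_forces(positions, params)
    e2, f2 = angle_energy_forces(positions, params)
    e3, f3 = excluded_volume_energy_forces(positions, params)
    return e1 + e2 + e3, f1 + f2 + f3
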