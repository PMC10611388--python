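"""Reduced-unit system and shared parameter types.

All internal computation uses reduced units in which the bead diameter
``sigma``, the bond length ``l`` and the thermal energy ``epsilon_0 = k_B T``
are unity.  Physical units enter only at the I/O boundary through
:class:`UnitSystem`, which fixes the physical length of one sigma (2.5 nm for
the dsDNA coarse-graining used here), the viscosity of the medium and the
temperature.  The reduced time unit is the Brownian time of a single bead,

    tau = 6 pi eta sigma^3 / epsilon_0,

about 74 ns for sigma = 2.5 nm in water at room temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "BOLTZMANN_J_PER_K",
    "UnitSystem",
    "ForceFieldParams",
    "SimConfig",
    "tau_physical",
    "velocity_to_physical",
    "velocity_to_reduced",
]

BOLTZMANN_J_PER_K = 1.380649e-23  # exact SI value


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between reduced simulation units and physical units.

    Parameters
    ----------
    sigma_nm : float
        Physical length of one reduced length unit sigma, in nanometres.
        Default 2.5 nm (the width of hydrated dsDNA).
    eta_cP : float
        Viscosity of the implicit medium in centipoise; 1 cP is pure water.
    temperature_K : float
        Absolute temperature defining the energy unit epsilon_0 = k_B*T.
    """

    sigma_nm: float = 2.5
    eta_cP: float = 1.0
    temperature_K: float = 293.0

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise ValueError(f"sigma_nm must be positive, got {self.sigma_nm}")
        if self.eta_cP <= 0:
            raise ValueError(f"eta_cP must be positive, got {self.eta_cP}")
        if self.temperature_K <= 0:
            raise ValueError(
                f"temperature_K must be positive, got {self.temperature_K}"
            )

    @property
    def epsilon0_J(self) -> float:
        """Thermal energy k_B*T in joules."""
        return BOLTZMANN_J_PER_K * self.temperature_K

    @property
    def tau_ns(self) -> float:
        """Reduced time unit 6*pi*eta*sigma^3/epsilon_0, in nanoseconds."""
        return tau_physical(self)

    def with_viscosity(self, eta_cP: float) -> "UnitSystem":
        return replace(self, eta_cP=eta_cP)


def tau_physical(units: UnitSystem) -> float:
    """Physical duration of one reduced time unit, in nanoseconds.

    tau = 6*pi*eta*sigma^3 / (k_B*T); strictly increasing in eta and sigma,
    strictly decreasing in T, and exactly linear in eta.
    """
    eta_Pa_s = units.eta_cP * 1.0e-3          # 1 cP = 1 mPa s
    sigma_m = units.sigma_nm * 1.0e-9
    tau_s = 6.0 * math.pi * eta_Pa_s * sigma_m**3 / units.epsilon0_J
    return tau_s * 1.0e9


def velocity_to_physical(v_reduced: float, units: UnitSystem) -> float:
    """Convert a velocity from sigma/tau to micrometres per second."""
    nm_per_ns = v_reduced * units.sigma_nm / tau_physical(units)
    # 1 nm/ns = 1 m/s = 1e6 um/s
    return nm_per_ns * 1.0e6


def velocity_to_reduced(v_um_per_s: float, units: UnitSystem) -> float:
    """Inverse of :func:`velocity_to_physical`."""
    return v_um_per_s / 1.0e6 * tau_physical(units) / units.sigma_nm


@dataclass(frozen=True)
class ForceFieldParams:
    """Bonded and nonbonded interaction constants of the bead-spring chain.

    The stiff bond constant (K_s = 80 epsilon_0/sigma^2) exists to prevent
    artificial strand passages under compression; the angular constant
    (K_b = 20 epsilon_0/rad^2 under the half-prefactor convention
    U = K_b/2 (theta - theta0)^2) sets the persistence length to about
    K_b * l = 20 sigma.
    """

    K_s: float = 80.0
    r0: float = 1.0
    K_b: float = 20.0
    theta0: float = math.pi
    lj_epsilon: float = 1.0
    lj_sigma: float = 1.0
    exclude_bonded: bool = True

    def __post_init__(self) -> None:
        for name in ("K_s", "r0", "K_b", "lj_epsilon", "lj_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.theta0 <= math.pi):
            raise ValueError(f"theta0 must lie in (0, pi], got {self.theta0}")

    @property
    def lj_cutoff(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.lj_sigma


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for a Langevin run.

    ``n_beads`` counts chain beads only; the piston is an extra bead managed
    by the dynamics module.  The seed fully determines the noise stream.
    """

    n_beads: int = 300
    dt: float = 0.010
    gamma: float = 1.0
    mass: float = 1.0
    gamma_piston: float | None = None
    mass_piston: float | None = None
    n_steps: int = 1_000_000
    sample_every: int = 10_000
    pre_equilibration_steps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_beads < 3:
            raise ValueError(f"need at least 3 beads, got {self.n_beads}")
        if self.n_steps <= 0 or self.sample_every <= 0:
            raise ValueError("n_steps and sample_every must be positive")
        if self.n_steps % self.sample_every != 0:
            raise ValueError(
                f"sample_every ({self.sample_every}) must divide "
                f"n_steps ({self.n_steps})"
            )
        if self.gamma <= 0 or self.mass <= 0:
            raise ValueError("gamma and mass must be positive")

    @property
    def effective_gamma_piston(self) -> float:
        return self.gamma if self.gamma_piston is None else self.gamma_piston

    @property
    def effective_mass_piston(self) -> float:
        return self.mass if self.mass_piston is None else self.mass_piston
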