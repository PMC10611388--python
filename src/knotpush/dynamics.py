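"""Langevin integrator, piston pushing protocol and trajectory sampling.

Each bead obeys the Langevin equation

    m r''  =  -grad U(r)  -  gamma m r'  +  sqrt(2 epsilon_0 m gamma) R(t)
              (+ F_ext on the piston only),

integrated with the BAOAB splitting of the velocity Verlet scheme, which is
accurate and stable at dt = 0.01 with the stiff K_s = 80 bonds.  The piston
is an extra bead whose y/z position and velocity are projected to zero after
every update, realising the on-axis constraint exactly.

A pushing run consists of a pre-equilibration segment with the external
force switched off, followed by production with the force on; frames are
sampled on a fixed stride.  The random stream is fully determined by the
seed, so identical configurations reproduce bit-identical trajectories on
one platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _core
from .channel import ChannelSpec
from .forcefield import (
    PistonSpec,
    angle_energy_forces,
    bond_energy_forces,
    excluded_volume_energy_forces,
)
from .units import ForceFieldParams, SimConfig

__all__ = [
    "ChainState",
    "Trajectory",
    "IntegrationError",
    "initialize_push",
    "initialize_free_chain",
    "langevin_step",
    "run_push",
    "run_free_chain",
    "piston_velocity",
]


class IntegrationError(RuntimeError):
    """Integration failed (blow-up, escaped bead or list overflow)."""

    def __init__(self, message: str, step: int, bead: int,
                 partial: Optional["Trajectory"] = None) -> None:
        super().__init__(message)
        self.step = step
        self.bead = bead
        self.partial = partial


@dataclass
class ChainState:
    """Positions and velocities of chain beads (+ piston last, if any)."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    step_index: int = 0
    has_piston: bool = False

    @property
    def n_chain(self) -> int:
        return self.positions.shape[0] - (1 if self.has_piston else 0)

    @property
    def chain_positions(self) -> np.ndarray:
        return self.positions[: self.n_chain]

    @property
    def piston_x(self) -> float:
        if not self.has_piston:
            raise ValueError("state has no piston")
        return float(self.positions[-1, 0])

    def copy(self) -> "ChainState":
        return ChainState(
            self.positions.copy(), self.velocities.copy(),
            self.time, self.step_index, self.has_piston,
        )


@dataclass
class Trajectory:
    """Time-ordered sampled frames of one run, with reproduction metadata."""

    frames: np.ndarray            # (n_frames, n_beads_total, 3)
    times: np.ndarray             # (n_frames,)
    n_chain: int
    has_piston: bool
    config: SimConfig
    channel: Optional[ChannelSpec] = None
    piston: Optional[PistonSpec] = None
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def chain_frames(self) -> np.ndarray:
        return self.frames[:, : self.n_chain, :]

    @property
    def piston_x_series(self) -> np.ndarray:
        if not self.has_piston:
            raise ValueError("trajectory has no piston")
        return self.frames[:, -1, 0]


def _maxwell_boltzmann(rng: np.random.Generator, n: int, mass: float,
                       kT: float = 1.0) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(kT / mass), size=(n, 3))


def initialize_push(
    config: SimConfig,
    channel: ChannelSpec,
    piston: PistonSpec,
    rng: np.random.Generator | None = None,
) -> ChainState:
    """Straight on-axis chain at x = 1..N with the piston beyond the end.

    The piston center sits at contact distance plus 1 sigma clearance from
    the last bead; velocities are Maxwell-Boltzmann at epsilon_0 (seeded).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_beads
    pos = np.zeros((n + 1, 3))
    pos[:n, 0] = np.arange(1, n + 1, dtype=float)
    x_p = piston.x_init
    if x_p is None:
        x_p = n + piston.contact_sigma + 1.0
    pos[n, 0] = x_p
    vel = np.empty((n + 1, 3))
    vel[:n] = _maxwell_boltzmann(rng, n, config.mass)
    vel[n] = _maxwell_boltzmann(rng, 1, config.effective_mass_piston)[0]
    vel[n, 1] = vel[n, 2] = 0.0
    return ChainState(pos, vel, has_piston=True)


def initialize_free_chain(
    config: SimConfig, rng: np.random.Generator | None = None
) -> ChainState:
    """Straight free chain (no channel, no piston) for equilibrium runs."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_beads
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(1, n + 1, dtype=float)
    vel = _maxwell_boltzmann(rng, n, config.mass)
    return ChainState(pos, vel, has_piston=False)


def langevin_step(
    state: ChainState,
    config: SimConfig,
    rng: np.random.Generator,
    params: ForceFieldParams | None = None,
    forces: np.ndarray | None = None,
    kT: float = 1.0,
) -> ChainState:
    """One BAOAB update of a piston-free state (numpy reference path).

    Used for small deterministic checks; production runs go through the
    numba kernel in :func:`run_push` / :func:`run_free_chain`.  ``forces``
    may carry precomputed forces for the current positions.
    """
    params = params or ForceFieldParams()
    s = state.copy()
    dt = config.dt
    m = config.mass

    def total_forces(pos: np.ndarray) -> np.ndarray:
        if pos.shape[0] < 2:
            return np.zeros_like(pos)
        f = bond_energy_forces(pos, params)[1]
        if pos.shape[0] >= 3:
            f += angle_energy_forces(pos, params)[1]
        f += excluded_volume_energy_forces(pos, params)[1]
        return f

    f = forces if forces is not None else total_forces(s.positions)
    s.velocities += 0.5 * dt * f / m
    s.positions += 0.5 * dt * s.velocities
    c1 = math.exp(-config.gamma * dt)
    c2 = math.sqrt(kT * (1.0 - c1 * c1) / m)
    s.velocities = c1 * s.velocities + c2 * rng.standard_normal(
        s.velocities.shape
    )
    s.positions += 0.5 * dt * s.velocities
    f = total_forces(s.positions)
    s.velocities += 0.5 * dt * f / m
    s.time += dt
    s.step_index += 1
    if not np.all(np.isfinite(s.positions)):
        raise IntegrationError("non-finite coordinates after step",
                               s.step_index, -1)
    return s


def _run_kernel(
    state: ChainState,
    config: SimConfig,
    params: ForceFieldParams,
    channel: Optional[ChannelSpec],
    piston: Optional[PistonSpec],
    F_ext: float,
    n_steps: int,
    sample_every: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Drive the numba integrator for one segment, mutating ``state``."""
    n_chain = state.n_chain
    has_channel = channel is not None
    has_piston = state.has_piston
    R_ch = channel.R_ch if has_channel else 0.0
    R_H = channel.R_H if has_channel else 0.0
    k_pitch = channel.k if has_channel else 1.0
    w_sign = float(channel.handedness) if has_channel else 1.0

    t_warm = np.zeros(n_chain)
    if has_channel and R_H > 0.0:
        for i in range(n_chain):
            t_warm[i] = _core.helix_multistart(
                state.positions[i, 0], state.positions[i, 1],
                state.positions[i, 2], R_H, k_pitch, w_sign, 4,
            )

    n_frames = n_steps // sample_every
    n_tot = state.positions.shape[0]
    frames = np.zeros((n_frames, n_tot, 3))
    frame_times = np.zeros(n_frames)

    status, info_step, info_bead = _core.run_segment(
        state.positions, state.velocities, n_chain,
        config.dt, n_steps, sample_every,
        params.K_s, params.r0, params.K_b, params.exclude_bonded,
        config.gamma, config.mass,
        config.effective_gamma_piston, config.effective_mass_piston,
        has_channel, R_ch, R_H, k_pitch, w_sign, t_warm,
        has_piston, piston.contact_sigma if piston else 0.0, F_ext,
        1.0, rng, frames, frame_times, state.time,
        25, 0.4,
    )
    if status != 0:
        messages = {
            1: "integration blow-up (non-finite coordinates)",
            2: "bead escaped the channel tube or degenerate geometry",
            3: "neighbour-list overflow",
        }
        raise IntegrationError(
            f"{messages.get(status, 'unknown failure')} at step "
            f"{info_step}, bead {info_bead}",
            info_step, info_bead,
        )
    state.time = frame_times[-1] if n_frames else state.time + n_steps * config.dt
    state.step_index += n_steps
    return frames, frame_times


def run_push(
    config: SimConfig,
    channel: ChannelSpec,
    piston: PistonSpec,
    params: ForceFieldParams | None = None,
) -> Trajectory:
    """Pre-equilibrate with the force off, then push; sample production.

    The returned trajectory contains the production-start frame followed by
    one frame every ``config.sample_every`` steps; chain beads come first,
    the piston is the last entry of each frame.
    """
    params = params or ForceFieldParams()
    rng = np.random.default_rng(config.seed)
    state = initialize_push(config, channel, piston, rng)

    if config.pre_equilibration_steps > 0:
        _run_kernel(
            state, config, params, channel, piston, 0.0,
            config.pre_equilibration_steps,
            config.pre_equilibration_steps, rng,
        )
        state.time = 0.0  # production clock starts after pre-equilibration

    first = state.positions.copy()[None, :, :]
    first_t = np.array([0.0])
    frames, times = _run_kernel(
        state, config, params, channel, piston, piston.F_ext,
        config.n_steps, config.sample_every, rng,
    )
    return Trajectory(
        frames=np.concatenate([first, frames]),
        times=np.concatenate([first_t, times]),
        n_chain=config.n_beads,
        has_piston=True,
        config=config,
        channel=channel,
        piston=piston,
        seed=config.seed,
        metadata={
            "pre_equilibration_steps": config.pre_equilibration_steps,
            "F_ext": piston.F_ext,
        },
    )


def run_free_chain(
    config: SimConfig, params: ForceFieldParams | None = None
) -> Trajectory:
    """Equilibrium run of an unconfined, unforced chain (for persistence)."""
    params = params or ForceFieldParams()
    rng = np.random.default_rng(config.seed)
    state = initialize_free_chain(config, rng)
    if config.pre_equilibration_steps > 0:
        _run_kernel(
            state, config, params, None, None, 0.0,
            config.pre_equilibration_steps,
            config.pre_equilibration_steps, rng,
        )
        state.time = 0.0
    frames, times = _run_kernel(
        state, config, params, None, None, 0.0,
        config.n_steps, config.sample_every, rng,
    )
    return Trajectory(
        frames=frames, times=times, n_chain=config.n_beads,
        has_piston=False, config=config, seed=config.seed,
    )


def piston_velocity(trajectory: Trajectory) -> float:
    """Mean piston speed |x_P(end) - x_P(start)| / elapsed time, sigma/tau."""
    if trajectory.n_frames < 2:
        raise ValueError("need at least two frames to compute a velocity")
    x = trajectory.piston_x_series
    dt = float(trajectory.times[-1] - trajectory.times[0])
    return abs(float(x[-1] - x[0])) / dt
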