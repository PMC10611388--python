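"""Configuration parsing, trajectory I/O and run manifests.

Configs are YAML with five optional sections (``units``, ``forcefield``,
``sim``, ``channel``, ``piston``); an empty file yields the full default
parameter set (N = 300, K_s = 80, K_b = 20, theta0 = pi, dt = 0.01,
sigma_P = 100, R_H = R_ch/3, one helical turn per diameter).  Unknown keys
raise a validation error naming the key.

Trajectories are written as multi-frame XYZ text (chain beads tagged ``C``,
the piston ``P``) plus a JSON sidecar carrying times, seed, geometry and a
config hash; ``read_trajectory(write_trajectory(t))`` restores coordinates
to float-text precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .channel import ChannelSpec, build_channel
from .dynamics import Trajectory
from .forcefield import PistonSpec
from .units import ForceFieldParams, SimConfig, UnitSystem

__all__ = [
    "RunSetup",
    "RunManifest",
    "ConfigError",
    "parse_config",
    "write_config",
    "write_trajectory",
    "read_trajectory",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class RunSetup:
    """Complete validated parameter bundle for one run."""

    units: UnitSystem = field(default_factory=UnitSystem)
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    sim: SimConfig = field(default_factory=SimConfig)
    channel: ChannelSpec = field(default_factory=ChannelSpec)
    piston: PistonSpec = field(default_factory=PistonSpec)

    def to_dict(self) -> dict:
        return {
            "units": dataclasses.asdict(self.units),
            "forcefield": dataclasses.asdict(self.forcefield),
            "sim": dataclasses.asdict(self.sim),
            "channel": dataclasses.asdict(self.channel),
            "piston": dataclasses.asdict(self.piston),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_CHANNEL_BUILD_KEYS = {"D_over_P", "P", "RH_ratio", "pitch_mode", "d_H"}


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'"
        )
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section '{section}': {exc}")


def _build_channel_section(data: dict) -> ChannelSpec:
    if not data:
        return ChannelSpec()
    if _CHANNEL_BUILD_KEYS & set(data):
        allowed = _CHANNEL_BUILD_KEYS | {"handedness"}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(
                f"unknown key(s) {sorted(unknown)} in section 'channel'"
            )
        try:
            return build_channel(**data)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"invalid channel parameters: {exc}")
    return _build_section(ChannelSpec, data, "channel")


def parse_config(path: str | Path) -> RunSetup:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping of sections")
    known = {"units", "forcefield", "sim", "channel", "piston"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config section(s) {sorted(unknown)}")
    return RunSetup(
        units=_build_section(UnitSystem, raw.get("units") or {}, "units"),
        forcefield=_build_section(
            ForceFieldParams, raw.get("forcefield") or {}, "forcefield"
        ),
        sim=_build_section(SimConfig, raw.get("sim") or {}, "sim"),
        channel=_build_channel_section(raw.get("channel") or {}),
        piston=_build_section(PistonSpec, raw.get("piston") or {}, "piston"),
    )


def write_config(setup: RunSetup, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(setup.to_dict(), sort_keys=True))


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Multi-frame XYZ plus a JSON sidecar (<path>.json)."""
    path = Path(path)
    n_tot = trajectory.frames.shape[1]
    with open(path, "w") as fh:
        for i in range(trajectory.n_frames):
            fh.write(f"{n_tot}\n")
            fh.write(f"time={trajectory.times[i]:.6f}\n")
            for j in range(n_tot):
                tag = (
                    "P"
                    if trajectory.has_piston and j == n_tot - 1
                    else "C"
                )
                x, y, z = trajectory.frames[i, j]
                fh.write(f"{tag} {x:.9f} {y:.9f} {z:.9f}\n")
    sidecar = {
        "n_chain": trajectory.n_chain,
        "has_piston": trajectory.has_piston,
        "n_frames": trajectory.n_frames,
        "times": [float(t) for t in trajectory.times],
        "seed": trajectory.seed,
        "sim": dataclasses.asdict(trajectory.config),
        "channel": (
            dataclasses.asdict(trajectory.channel)
            if trajectory.channel
            else None
        ),
        "piston": (
            dataclasses.asdict(trajectory.piston)
            if trajectory.piston
            else None
        ),
        "metadata": trajectory.metadata,
        "version": __version__,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise IOError(f"missing trajectory sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            break
        n = int(lines[k])
        atom_lines = lines[k + 2 : k + 2 + n]
        if len(atom_lines) != n:
            raise IOError("truncated trajectory file")
        frame = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in atom_lines]
        )
        frames.append(frame)
        k += 2 + n
    frames = np.array(frames)
    if len(frames) != meta["n_frames"]:
        raise IOError(
            f"frame count mismatch: file has {len(frames)}, sidecar says "
            f"{meta['n_frames']}"
        )
    return Trajectory(
        frames=frames,
        times=np.array(meta["times"]),
        n_chain=meta["n_chain"],
        has_piston=meta["has_piston"],
        config=SimConfig(**meta["sim"]),
        channel=ChannelSpec(**meta["channel"]) if meta["channel"] else None,
        piston=PistonSpec(**meta["piston"]) if meta["piston"] else None,
        seed=meta["seed"],
        metadata=meta.get("metadata", {}),
    )


@dataclass
class RunManifest:
    """Reproduction record written before and finalised after each run."""

    setup: dict
    seed: int
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    status: str = "pending"
    started_at: float = field(default_factory=time.time)
    finished_at: Optional[float] = None
    wall_time_s: Optional[float] = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    def finalize(self, path: str | Path, status: str = "completed") -> None:
        self.status = status
        self.finished_at = time.time()
        self.wall_time_s = self.finished_at - self.started_at
        self.write(path)

    @staticmethod
    def read(path: str | Path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))
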