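"""Shared fixtures.

The expensive piston-pushing ensembles (compression-scaling sweep and the
chirality study) are session-scoped so the acceptance tests and the trend
tests share one set of runs.
"""

from __future__ import annotations

import numpy as np
import pytest

import knotpush as kp
from knotpush.channel import build_channel
from knotpush.forcefield import PistonSpec
from knotpush.metrics import span
from knotpush.topology import load_tables
from knotpush.units import SimConfig


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


# ------------------------------------------------------------------ runs ---

COMPRESSION_FORCES = (0.5, 1.0, 2.0, 5.0)
# weak pushes converge slowly and their spans fluctuate on ~5e5-step
# timescales, so they get much longer production and more seeds
COMPRESSION_STEPS = {0.5: 8_000_000, 1.0: 4_000_000, 2.0: 1_500_000,
                     5.0: 1_000_000}
COMPRESSION_SEEDS = {0.5: (1, 2, 3, 4, 5), 1.0: (1, 2, 3, 4, 5),
                     2.0: (1, 2, 3), 5.0: (1, 2, 3)}


def run_compression_sweep():
    """Cylinder pushing sweep (N=100, D/P=1) used for the scaling fit."""
    channel = build_channel(handedness=1, D_over_P=1.0, P=20.0, RH_ratio=0.0)
    out = {}
    for F in COMPRESSION_FORCES:
        runs = []
        for seed in COMPRESSION_SEEDS[F]:
            cfg = SimConfig(
                n_beads=100,
                n_steps=COMPRESSION_STEPS[F],
                sample_every=COMPRESSION_STEPS[F] // 100,
                pre_equilibration_steps=100_000,
                seed=seed,
            )
            traj = kp.run_push(cfg, channel, PistonSpec(F_ext=F))
            runs.append(traj)
        out[F] = runs
    return channel, out


@pytest.fixture(scope="session")
def compression_sweep():
    return run_compression_sweep()


def steady_spans(sweep) -> tuple[np.ndarray, np.ndarray]:
    """Mean steady-state span (last half of production) per force."""
    channel, runs_by_force = sweep
    forces, spans = [], []
    for F, runs in runs_by_force.items():
        per_run = []
        for traj in runs:
            frames = traj.chain_frames
            half = [span(f) for f in frames[len(frames) // 2:]]
            per_run.append(float(np.mean(half)))
        forces.append(F)
        spans.append(float(np.mean(per_run)))
    return np.array(spans), np.array(forces)
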