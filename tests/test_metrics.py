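"""Polymer metrics: span, sizes, distributions, persistence, scaling fit."""

import numpy as np
import pytest

from knotpush.channel import ChannelSpec, build_channel, helix_point
from knotpush.dynamics import Trajectory, run_free_chain
from knotpush.fixtures import hairpin_chain
from knotpush.forcefield import PistonSpec
from knotpush.metrics import (
    axial_distribution,
    chain_size,
    fit_compression_scaling,
    index_position_projection,
    periodized_heatmap,
    persistence_length,
    radial_distribution,
    span,
    steady_state_span,
)
from knotpush.units import ForceFieldParams, SimConfig


def _mk_traj(frames, channel=None, piston=None, n_chain=None,
             has_piston=False):
    frames = np.asarray(frames, dtype=float)
    n_chain = n_chain if n_chain is not None else frames.shape[1]
    return Trajectory(
        frames=frames,
        times=np.arange(frames.shape[0], dtype=float) + 1.0,
        n_chain=n_chain,
        has_piston=has_piston,
        config=SimConfig(n_beads=max(n_chain, 3), n_steps=10,
                         sample_every=10),
        channel=channel,
        piston=piston,
    )


class TestSpanAndSize:
    def test_straight_chain_span(self):
        pos = np.column_stack([np.arange(1.0, 301.0), np.zeros(300),
                               np.zeros(300)])
        assert span(pos) == pytest.approx(299.0)

    def test_common_x_gives_zero(self):
        pos = np.column_stack([np.full(10, 2.0), np.arange(10.0),
                               np.zeros(10)])
        assert span(pos) == 0.0

    def test_equals_pairwise_max(self, rng):
        for _ in range(20):
            pos = rng.normal(size=(30, 3)) * 10
            x = pos[:, 0]
            brute = max(abs(a - b) for a in x for b in x)
            assert span(pos) == pytest.approx(brute)

    def test_empty_frame_raises(self):
        with pytest.raises(ValueError):
            span(np.zeros((0, 3)))

    def test_end_to_end_and_gyration(self, rng):
        pos = np.column_stack([np.arange(1.0, 11.0), np.zeros(10),
                               np.zeros(10)])
        e2e, rg = chain_size(pos)
        assert e2e == pytest.approx(9.0)
        two = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert chain_size(two)[1] == pytest.approx(1.5)  # d/2
        # direct double-sum identity: Rg^2 = (1/2N^2) sum_ij |ri-rj|^2
        pos = rng.normal(size=(25, 3))
        _, rg = chain_size(pos)
        diffs = pos[:, None, :] - pos[None, :, :]
        rg2 = np.sum(diffs ** 2) / (2 * 25 ** 2)
        assert rg ** 2 == pytest.approx(rg2, rel=1e-10)


class TestRadialDistribution:
    def test_on_axis_mass_in_first_bin(self):
        ch = ChannelSpec(R_ch=10.0, R_H=0.0)
        frames = np.zeros((3, 10, 3))
        frames[:, :, 0] = np.arange(10.0)
        traj = _mk_traj(frames, channel=ch)
        _, freq = radial_distribution(traj, ch, n_bins=20)
        assert freq[0] == pytest.approx(1.0)
        assert freq.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_disk_scales_with_annulus_area(self, rng):
        ch = ChannelSpec(R_ch=1.0, R_H=0.0)
        n = 200_000
        r = np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        frames = np.zeros((1, n, 3))
        frames[0, :, 1] = r * np.cos(th)
        frames[0, :, 2] = r * np.sin(th)
        traj = _mk_traj(frames, channel=ch)
        centers, freq = radial_distribution(traj, ch, n_bins=10)
        edges = np.linspace(0, 1, 11)
        areas = np.diff(edges ** 2)  # annulus area (up to pi)
        np.testing.assert_allclose(freq, areas / areas.sum(), atol=0.01)

    def test_escaped_bead_rejected(self):
        ch = ChannelSpec(R_ch=1.0, R_H=0.0)
        frames = np.zeros((1, 2, 3))
        frames[0, 1, 1] = 2.0
        with pytest.raises(ValueError):
            radial_distribution(_mk_traj(frames, channel=ch), ch)


class TestAxialDistribution:
    def _piston_traj(self, chain_x, piston_x):
        n = len(chain_x)
        frames = np.zeros((1, n + 1, 3))
        frames[0, :n, 0] = chain_x
        frames[0, n, 0] = piston_x
        return _mk_traj(frames, piston=PistonSpec(sigma_P=100.0),
                        n_chain=n, has_piston=True)

    def test_beads_at_face_give_zero_offset(self):
        piston_x = 100.0
        face = piston_x - 50.5 + 0.5
        traj = self._piston_traj([face] * 5, piston_x)
        centers, counts = axial_distribution(traj, n_bins=11,
                                             range_sigma=(-1.0, 1.0))
        assert counts.sum() == 5
        assert counts[5] == 5  # central bin holds the delta

    def test_sign_convention_and_conservation(self):
        piston_x = 100.0
        face = piston_x - 50.5 + 0.5
        # one bead ahead of the face (pushed), one behind (not contacted)
        traj = self._piston_traj([face - 5.0, face + 5.0], piston_x)
        centers, counts = axial_distribution(traj, n_bins=4,
                                             range_sigma=(-10, 10))
        ahead = centers > 0
        assert counts[ahead].sum() == 1 and counts[~ahead].sum() == 1
        assert counts.sum() == 2  # beads x frames


class TestPeriodizedHeatmap:
    def test_centerline_beads_trace_constant_transverse(self):
        ch = build_channel(handedness=1, D_over_P=1.0, P=20.0,
                          RH_ratio=1 / 3)
        ts = np.linspace(0, 6 * np.pi, 500)
        frames = helix_point(ch, ts)[None, :, :]
        traj = _mk_traj(frames, channel=ch)
        xe, te, counts = periodized_heatmap(traj, ch, 10, 16)
        assert counts.sum() == 500
        occupied = np.nonzero(counts.sum(axis=0))[0]
        # all mass in the transverse bin(s) containing +R_H
        centers = 0.5 * (te[:-1] + te[1:])
        assert np.all(np.abs(centers[occupied] - ch.R_H) < 2 * (te[1] - te[0]))

    def test_translation_by_one_turn_invariant(self, rng):
        ch = build_channel(handedness=-1, D_over_P=1.0, P=20.0,
                          RH_ratio=1 / 3)
        pos = rng.normal(scale=2.0, size=(1, 200, 3))
        shifted = pos + np.array([ch.d_H, 0.0, 0.0])
        h1 = periodized_heatmap(_mk_traj(pos, channel=ch), ch)[2]
        h2 = periodized_heatmap(_mk_traj(shifted, channel=ch), ch)[2]
        np.testing.assert_allclose(h1, h2)


class TestIndexProjection:
    def test_straight_chain_monotone(self):
        pos = np.column_stack([np.arange(1.0, 21.0), np.zeros(20),
                               np.zeros(20)])
        proj = index_position_projection(pos)
        assert proj.shape == (20, 2)
        assert np.all(np.diff(proj[:, 1]) > 0)

    def test_hairpin_has_one_fold(self):
        pos = hairpin_chain(40, 25)
        proj = index_position_projection(pos)
        signs = np.sign(np.diff(proj[:, 1]))
        changes = np.sum(np.abs(np.diff(signs[signs != 0])) > 0)
        assert changes == 1
        assert span(pos) == pytest.approx(max(25, 15) - 1)


@pytest.fixture(scope="module")
def free_runs():
    out = {}
    for kb in (20.0, 40.0):
        cfg = SimConfig(n_beads=80, n_steps=600_000, sample_every=3_000,
                        pre_equilibration_steps=150_000, seed=21)
        out[kb] = run_free_chain(cfg, ForceFieldParams(K_b=kb))
    return out


class TestPersistenceLength:
    def test_default_stiffness_gives_20_sigma(self, free_runs):
        P = persistence_length(free_runs[20.0])
        assert P == pytest.approx(20.0, rel=0.10)

    def test_doubling_stiffness_doubles_persistence(self, free_runs):
        P20 = persistence_length(free_runs[20.0])
        P40 = persistence_length(free_runs[40.0], max_lag=8)
        assert P40 / P20 == pytest.approx(2.0, rel=0.2)

    def test_floppy_chain_short_persistence(self):
        cfg = SimConfig(n_beads=40, n_steps=200_000, sample_every=2_000,
                        pre_equilibration_steps=50_000, seed=3)
        traj = run_free_chain(cfg, ForceFieldParams(K_b=0.0))
        P = persistence_length(traj, max_lag=2)
        assert P < 3.0  # near the freely jointed limit


class TestCompressionScalingFit:
    def test_exact_power_law_recovered(self):
        D = 20.0
        F = np.array([0.5, 1.0, 2.0, 5.0])
        S = 100.0 * (F * D) ** (-4.0 / 9.0)
        assert fit_compression_scaling(S, F, D) == pytest.approx(-9.0 / 4.0)

    def test_noisy_power_law_within_band(self, rng):
        D = 20.0
        F = np.array([0.5, 1.0, 2.0, 5.0])
        slopes = []
        for _ in range(100):
            S = 100.0 * (F * D) ** (-4.0 / 9.0)
            S = S * np.exp(rng.normal(scale=0.05, size=S.size))
            slopes.append(fit_compression_scaling(S, F, D))
        assert np.mean(slopes) == pytest.approx(-2.25, abs=0.2)

    def test_two_points_equal_log_ratio(self):
        D = 10.0
        S = np.array([50.0, 20.0])
        F = np.array([1.0, 4.0])
        expect = np.log(F[1] * D / (F[0] * D)) / np.log(S[1] / S[0])
        assert fit_compression_scaling(S, F, D) == pytest.approx(expect)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_compression_scaling(np.array([1.0, -1.0]),
                                    np.array([1.0, 2.0]), 10.0)


def test_steady_state_span_window():
    frames = np.zeros((10, 2, 3))
    frames[:, 1, 0] = np.linspace(100, 10, 10)  # decaying span
    traj = _mk_traj(frames)
    # last half mean of spans [50, 40, 30, 20, 10]
    assert steady_state_span(traj, 0.5) == pytest.approx(30.0)
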