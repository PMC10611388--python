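"""Force field: reference energies, exact gradients, kernel consistency."""

import math

import numpy as np
import pytest

from knotpush import _core
from knotpush.forcefield import (
    PistonSpec,
    angle_energy_forces,
    bond_energy_forces,
    excluded_volume_energy_forces,
    piston_energy_forces,
    total_internal_energy_forces,
)
from knotpush.units import ForceFieldParams

CUT = 2.0 ** (1.0 / 6.0)


def random_chain(rng, n=12, spacing=1.0):
    """Self-avoiding-ish random walk with unit-ish bonds."""
    pos = [np.zeros(3)]
    while len(pos) < n:
        step = rng.normal(size=3)
        step *= spacing / np.linalg.norm(step)
        cand = pos[-1] + step
        if all(np.linalg.norm(cand - p) > 0.8 for p in pos[:-1]):
            pos.append(cand)
    return np.array(pos)


class TestBond:
    def test_relaxed_chain_has_zero_energy(self):
        pos = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        e, f = bond_energy_forces(pos)
        assert e == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_stretched_bond_energy(self):
        pos = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        e, _ = bond_energy_forces(pos)
        assert e == pytest.approx(0.8)  # 80 * 0.1^2

    def test_forces_sum_to_zero(self, rng):
        pos = random_chain(rng)
        _, f = bond_energy_forces(pos)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12)

    def test_zero_length_bond_raises(self):
        with pytest.raises(FloatingPointError):
            bond_energy_forces(np.zeros((2, 3)))


class TestAngle:
    def test_straight_chain_zero(self):
        pos = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        e, f = angle_energy_forces(pos)
        assert e == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(f, 0.0, atol=1e-6)

    def test_right_angle_energy(self):
        pos = np.array([[0.0, 1, 0], [0, 0, 0], [1, 0, 0]])
        e, _ = angle_energy_forces(pos)
        # half convention: (K_b/2) (pi/2)^2 = 10 (pi/2)^2
        assert e == pytest.approx(10.0 * (math.pi / 2) ** 2)

    def test_net_force_and_torque_vanish(self, rng):
        pos = random_chain(rng, n=8)
        _, f = angle_energy_forces(pos)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)
        torque = np.cross(pos, f).sum(axis=0)
        np.testing.assert_allclose(torque, 0.0, atol=1e-10)


class TestExcludedVolume:
    def test_zero_at_cutoff(self):
        pos = np.array([[0.0, 0, 0], [CUT, 0, 0], [10, 10, 10]])
        e, f = excluded_volume_energy_forces(
            pos, ForceFieldParams(exclude_bonded=False)
        )
        assert e == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_unit_distance_energy(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0], [1.0, 0, 0]])
        # only pair (0, 2) is non-adjacent and within the cutoff
        e, _ = excluded_volume_energy_forces(pos)
        assert e == pytest.approx(1.0)  # 4*(1 - 1 + 1/4)

    def test_bonded_pairs_excluded_by_default(self):
        pos = np.array([[0.0, 0, 0], [0.9, 0, 0], [1.8, 0, 0]])
        e_excl, _ = excluded_volume_energy_forces(pos)
        e_incl, _ = excluded_volume_energy_forces(
            pos, ForceFieldParams(exclude_bonded=False)
        )
        assert e_excl == pytest.approx(0.0, abs=1e-12)
        assert e_incl > 0


class TestPiston:
    def test_contact_distance_zero_energy(self):
        piston = PistonSpec(sigma_P=100.0, F_ext=1.0)
        x = CUT * piston.contact_sigma
        e, f, fp = piston_energy_forces(np.array([[x, 0, 0]]), 0.0, piston)
        assert e == pytest.approx(0.0, abs=1e-10)

    def test_external_force_only_when_no_contact(self):
        piston = PistonSpec(sigma_P=100.0, F_ext=2.0)
        e, f, fp = piston_energy_forces(
            np.array([[300.0, 0, 0]]), 0.0, piston
        )
        assert e == 0.0
        np.testing.assert_array_equal(fp, [-2.0, 0.0, 0.0])

    def test_newton_third_law_before_external(self):
        piston = PistonSpec(sigma_P=100.0, F_ext=3.0)
        pos = np.array([[52.0, 1.0, -0.5], [53.0, -2.0, 0.3]])
        _, f, fp = piston_energy_forces(pos, 0.0, piston,
                                        include_external=False)
        np.testing.assert_allclose(f.sum(axis=0) + fp, 0.0, atol=1e-10)


class TestGradients:
    """Every analytic force is the exact negative gradient."""

    @pytest.mark.parametrize("term", [
        bond_energy_forces,
        angle_energy_forces,
        excluded_volume_energy_forces,
        total_internal_energy_forces,
    ])
    def test_matches_central_differences(self, term, rng):
        pos = random_chain(rng, n=9, spacing=1.02)
        e0, f0 = term(pos)
        h = 1e-6
        for i in range(pos.shape[0]):
            for d in range(3):
                dp = np.zeros_like(pos)
                dp[i, d] = h
                fd = -(term(pos + dp)[0] - term(pos - dp)[0]) / (2 * h)
                assert f0[i, d] == pytest.approx(fd, rel=2e-5, abs=2e-5)

    def test_piston_gradient(self, rng):
        piston = PistonSpec(sigma_P=100.0)
        pos = np.array([[52.0, 1.0, -0.5], [55.0, -2.0, 0.3]])
        _, f0, _ = piston_energy_forces(pos, 0.0, piston)
        h = 1e-6
        for i in range(2):
            for d in range(3):
                dp = np.zeros_like(pos)
                dp[i, d] = h
                ep = piston_energy_forces(pos + dp, 0.0, piston)[0]
                em = piston_energy_forces(pos - dp, 0.0, piston)[0]
                assert f0[i, d] == pytest.approx(
                    -(ep - em) / (2 * h), rel=1e-4, abs=1e-6
                )


class TestKernelConsistency:
    """The numba production kernel agrees with the reference implementation."""

    def test_forces_match_reference(self, rng):
        params = ForceFieldParams()
        for _ in range(10):
            pos = random_chain(rng, n=15, spacing=1.01)
            n = pos.shape[0]
            ref = total_internal_energy_forces(pos, params)[1]
            forces = np.zeros((n, 3))
            nbr = np.zeros((n, 64), dtype=np.int64)
            cnt = np.zeros(n, dtype=np.int64)
            r_list = CUT + 0.4
            assert _core.build_neighbor_list(
                pos, n, r_list * r_list, True, nbr, cnt
            ) == 0
            status, _ = _core.compute_forces(
                pos, forces, n, params.K_s, params.r0, params.K_b,
                False, 0.0, 0.0, 1.0, 1.0, np.zeros(n),
                False, False, 0.0, 0.0, nbr, cnt,
                np.full(n, -1.0), pos.copy(),
            )
            assert status == 0
            np.testing.assert_allclose(forces, ref, rtol=1e-9, atol=1e-9)

    def test_neighbor_list_equals_all_pairs(self, rng):
        """EV forces via the half list equal a direct all-pairs sum."""
        params = ForceFieldParams()
        done = 0
        while done < 50:
            pos = rng.uniform(0, 3.0, size=(20, 3))
            # keep bonded beads apart so the bond term stays finite
            pos[:, 0] += np.arange(20) * 1.0
            diffs = pos[:, None, :] - pos[None, :, :]
            dists = np.linalg.norm(diffs, axis=2)
            np.fill_diagonal(dists, np.inf)
            if dists.min() < 0.35:  # below the kernel's overlap clip
                continue
            done += 1
            ref = excluded_volume_energy_forces(pos, params)[1]
            n = pos.shape[0]
            forces = np.zeros((n, 3))
            nbr = np.zeros((n, 64), dtype=np.int64)
            cnt = np.zeros(n, dtype=np.int64)
            r_list = CUT + 0.4
            assert _core.build_neighbor_list(
                pos, n, r_list * r_list, True, nbr, cnt
            ) == 0
            _core.compute_forces(
                pos, forces, n, 0.0, 1.0, 0.0,  # disable bonds and angles
                False, 0.0, 0.0, 1.0, 1.0, np.zeros(n),
                False, False, 0.0, 0.0, nbr, cnt,
                np.full(n, -1.0), pos.copy(),
            )
            np.testing.assert_allclose(forces, ref, rtol=1e-9, atol=1e-9)
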