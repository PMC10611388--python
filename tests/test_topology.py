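"""Topology stack: diagrams, Jones polynomial, identification, writhe."""

import numpy as np
import pytest

from knotpush.fixtures import (
    figure_eight_curve,
    random_ring,
    rational_knot_curve,
    torus_knot_curve,
)
from knotpush.topology import (
    KnotDiagram,
    LaurentPoly,
    census,
    classify_groups,
    close_chain,
    compute_stats,
    gauss_writhe,
    handedness,
    identify_curve,
    identify_knot,
    jones_polynomial,
    kauffman_bracket,
    kauffman_bracket_recursive,
    project_to_diagram,
    simplify_diagram,
)
from knotpush.topology.analyze import TopologyResult
from knotpush.topology.jones import DiagramTooComplexError
from knotpush.channel import build_channel


def poly_from_t_powers(d):
    """Laurent polynomial from {power of t: coeff}."""
    return LaurentPoly.from_dict({4 * k: v for k, v in d.items()})


# frozen reference polynomials (standard knot-theory values)
V_TREFOIL_RIGHT = poly_from_t_powers({1: 1, 3: 1, 4: -1})
V_FIG8 = poly_from_t_powers({-2: 1, -1: -1, 0: 1, 1: -1, 2: 1})
V_5_1_RIGHT = poly_from_t_powers({2: 1, 4: 1, 5: -1, 6: 1, 7: -1})
V_5_2_RIGHT = poly_from_t_powers({1: 1, 2: -1, 3: 2, 4: -1, 5: 1, 6: -1})


class TestLaurentPoly:
    def test_arithmetic_and_mirror(self):
        p = poly_from_t_powers({1: 2, -1: 3})   # 2t + 3/t
        q = poly_from_t_powers({0: 1, 1: -2})   # 1 - 2t
        assert (p + q) == poly_from_t_powers({-1: 3, 0: 1})  # 2t cancels
        assert (p * q) == poly_from_t_powers({-1: 3, 0: -6, 1: 2, 2: -4})
        assert p.mirror() == poly_from_t_powers({-1: 2, 1: 3})
        assert V_FIG8.is_palindromic
        assert not V_TREFOIL_RIGHT.is_palindromic

    def test_key_round_trip(self):
        assert LaurentPoly.from_key(V_5_2_RIGHT.key()) == V_5_2_RIGHT

    def test_determinant_evaluation(self):
        assert abs(V_TREFOIL_RIGHT.evaluate_at_minus_one()) == 3
        assert abs(V_FIG8.evaluate_at_minus_one()) == 5


class TestProjection:
    def test_planar_circle_has_no_crossings(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        circle = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        d = project_to_diagram(circle, direction=np.array([0.05, 0.02, 1.0]),
                               rng=np.random.default_rng(0))
        assert d.n_crossings == 0

    def test_trefoil_minimal_diagram_all_same_sign(self):
        from knotpush.topology import best_diagram
        fx = torus_knot_curve(2, 3, "right")
        d = best_diagram(fx.vertices, n_projections=10,
                         rng=np.random.default_rng(1))
        assert d.n_crossings == 3
        assert set(d.signs.values()) == {1}

    def test_mirror_flips_all_signs(self):
        fx = torus_knot_curve(2, 3, "right")
        d = project_to_diagram(fx.vertices, rng=np.random.default_rng(1))
        m = d.mirror()
        assert all(
            m.signs[k] == -d.signs[k] for k in d.signs
        )


class TestSimplify:
    def test_single_kink_reduces_to_zero(self):
        # R1: one crossing visited twice in a row
        d = KnotDiagram(((0, True), (0, False)), {0: 1})
        assert simplify_diagram(d).n_crossings == 0

    def test_jittered_circles_reduce_to_unknot(self):
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        circle = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        rng = np.random.default_rng(12)
        for _ in range(100):
            noisy = circle + rng.normal(scale=0.01, size=circle.shape)
            d = simplify_diagram(project_to_diagram(noisy, rng=rng))
            assert d.n_crossings == 0

    def test_jones_invariant_under_simplification(self):
        for fx in (torus_knot_curve(2, 3, "right"), figure_eight_curve()):
            d = project_to_diagram(fx.vertices,
                                   rng=np.random.default_rng(3))
            assert jones_polynomial(simplify_diagram(d)) == jones_polynomial(d)


class TestJones:
    def test_unknot_is_one(self):
        d = KnotDiagram((), {})
        assert jones_polynomial(d) == LaurentPoly.one()

    @pytest.mark.parametrize("fx,expected", [
        (torus_knot_curve(2, 3, "right"), V_TREFOIL_RIGHT),
        (torus_knot_curve(2, 5, "right"), V_5_1_RIGHT),
        (figure_eight_curve(), V_FIG8),
    ])
    def test_reference_polynomials(self, fx, expected):
        d = simplify_diagram(
            project_to_diagram(fx.vertices, rng=np.random.default_rng(5))
        )
        assert jones_polynomial(d) == expected

    def test_mirror_inverts_variable(self):
        fx = rational_knot_curve("5_2")
        d = simplify_diagram(
            project_to_diagram(fx.vertices, rng=np.random.default_rng(6))
        )
        assert jones_polynomial(d.mirror()) == jones_polynomial(d).mirror()

    def test_dual_path_bracket_agreement(self):
        for fx in (torus_knot_curve(2, 3, "left"), figure_eight_curve(),
                   rational_knot_curve("6_2")):
            d = simplify_diagram(
                project_to_diagram(fx.vertices, rng=np.random.default_rng(7))
            )
            assert kauffman_bracket(d) == kauffman_bracket_recursive(d)

    def test_invariance_across_projections(self):
        fx = rational_knot_curve("7_4")
        rng = np.random.default_rng(8)
        polys = set()
        for _ in range(10):
            d = simplify_diagram(project_to_diagram(fx.vertices, rng=rng))
            polys.add(jones_polynomial(d).key())
        assert len(polys) == 1

    def test_crossing_cap_raises(self):
        fx = torus_knot_curve(2, 3, "right")
        d = project_to_diagram(fx.vertices, rng=np.random.default_rng(9))
        with pytest.raises(DiagramTooComplexError):
            jones_polynomial(d, max_crossings=2)


class TestIdentify:
    def test_unknot(self, tables):
        assert identify_knot(LaurentPoly.one(), tables) == ("0_1", False)

    def test_unmatched_polynomial_is_unidentified(self, tables):
        junk = poly_from_t_powers({0: 1, 1: 7})
        assert identify_knot(junk, tables)[0] == "?"

    def test_trefoil_hands(self, tables):
        right = torus_knot_curve(2, 3, "right")
        left = torus_knot_curve(2, 3, "left")
        rng = np.random.default_rng(10)
        name_r, mir_r, *_ = identify_curve(right.vertices, tables, rng=rng)
        name_l, mir_l, *_ = identify_curve(left.vertices, tables, rng=rng)
        assert name_r == name_l == "3_1"
        assert mir_r != mir_l
        assert handedness("3_1", mir_r, tables) == "right"
        assert handedness("3_1", mir_l, tables) == "left"

    def test_amphichiral_identifies_same_under_mirror(self, tables):
        fx = figure_eight_curve()
        rng = np.random.default_rng(11)
        a = identify_curve(fx.vertices, tables, rng=rng)
        b = identify_curve(fx.mirrored().vertices, tables, rng=rng)
        assert a[0] == b[0] == "4_1"
        assert handedness("4_1", a[1], tables) == "amphichiral"


class TestHandednessAndGroups:
    def test_flip_rule(self, tables):
        assert handedness("5_2", False, tables) == "right"
        assert handedness("5_2", True, tables) == "left"
        assert handedness("4_1", True, tables) == "amphichiral"
        assert handedness("unknown_name", False, tables) == "undetermined"

    def test_group_membership(self, tables):
        assert classify_groups("3_1", tables) == {"torus", "twist"}
        assert classify_groups("4_1", tables) == {"twist", "amphichiral"}
        assert classify_groups("6_2", tables) == frozenset()
        assert classify_groups("no_such", tables) == frozenset()

    def test_census_totals(self, tables):
        counts = census(tables)
        assert counts["total"] == 801
        assert counts["groups"]["amphichiral"] == 20
        assert sum(counts["per_crossing_number"].values()) == counts["total"]


class TestCloseChain:
    def test_ligation_filter_rejects_far_ends(self):
        chain = np.zeros((10, 3))
        chain[:, 0] = np.linspace(0, 12, 10)
        assert close_chain(chain, ligation_distance=10.0) is None

    def test_coincident_ends_direct_join(self):
        t = np.linspace(0, 2 * np.pi, 50)
        ring = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        closed = close_chain(ring, ligation_distance=10.0)
        assert closed is not None
        assert closed.vertices.shape[0] == 49  # duplicate end dropped

    def test_near_circle_closes_to_unknot(self, tables):
        t = np.linspace(0, 1.9 * np.pi, 60)
        arc = np.column_stack([5 * np.cos(t), 5 * np.sin(t),
                               np.zeros_like(t)])
        closed = close_chain(arc, ligation_distance=10.0)
        name, *_ = identify_curve(closed.vertices, tables,
                                  rng=np.random.default_rng(12))
        assert name == "0_1"

    def test_closure_of_trefoil_arc_preserves_knot(self, tables):
        fx = torus_knot_curve(2, 3, "right", n_points=300)
        arc = fx.vertices  # open it: endpoints are adjacent vertices
        closed = close_chain(arc, ligation_distance=10.0)
        name, mirror, *_ = identify_curve(closed.vertices, tables,
                                          rng=np.random.default_rng(13))
        assert name == "3_1"


class TestWrithe:
    def test_planar_curves_vanish(self, rng):
        for _ in range(5):
            t = np.sort(rng.uniform(0, 2 * np.pi, 80))
            curve = np.column_stack(
                [np.cos(t) * rng.uniform(1, 3), np.sin(t), np.zeros_like(t)]
            )
            assert abs(gauss_writhe(curve)) < 1e-10

    def test_mirror_antisymmetry_exact(self, rng):
        curve = rng.normal(size=(50, 3))
        m = curve * np.array([1.0, 1.0, -1.0])
        assert gauss_writhe(m) == pytest.approx(-gauss_writhe(curve),
                                                abs=1e-12)

    def test_torus_fixture_matches_quadrature(self):
        fx = torus_knot_curve(2, 3, "right", n_points=250)
        verts = fx.vertices
        wr = gauss_writhe(verts)
        assert wr > 0
        # independent oracle: Gauss-Legendre quadrature of the double
        # integral over every non-adjacent segment pair of the same polygon
        nodes, weights = np.polynomial.legendre.leggauss(8)
        s = 0.5 * (nodes + 1.0)
        w8 = 0.5 * weights
        n = verts.shape[0]
        starts = verts
        vecs = np.roll(verts, -1, axis=0) - verts
        total = 0.0
        for i in range(n - 1):
            a1 = starts[i][None] + s[:, None] * vecs[i][None]
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue
                a2 = starts[j][None] + s[:, None] * vecs[j][None]
                r = a1[:, None, :] - a2[None, :, :]
                norm = np.linalg.norm(r, axis=2) ** 3
                cr = np.cross(vecs[i], vecs[j])
                integrand = (r @ cr) / norm
                total += np.einsum("a,b,ab->", w8, w8, integrand)
        oracle = total / (2 * np.pi)
        assert wr == pytest.approx(oracle, abs=1e-3)


class TestStats:
    def test_equichiral_counting(self):
        ch = build_channel(handedness=1, D_over_P=1.0, RH_ratio=1 / 3)
        results = [
            TopologyResult(i, 0.0, 1.0, True, "3_1", False, "right")
            for i in range(6)
        ] + [
            TopologyResult(i + 6, 0.0, 1.0, True, "3_1", True, "left")
            for i in range(2)
        ]
        stats = compute_stats(results, ch)
        assert stats.n_equichiral == 6
        assert stats.n_antichiral == 2
        assert stats.equichiral_fraction == pytest.approx(0.75)
        assert stats.knotting_probability == 1.0

    def test_unknot_ensemble_probability_zero(self):
        results = [
            TopologyResult(i, 0.0, 1.0, True, "0_1", False, "amphichiral")
            for i in range(5)
        ]
        stats = compute_stats(results, None)
        assert stats.knotting_probability == 0.0

    def test_mirrored_writhes_negate(self, rng):
        vals = rng.normal(size=20)
        res = [TopologyResult(i, w, 1.0, False) for i, w in enumerate(vals)]
        resm = [TopologyResult(i, -w, 1.0, False)
                for i, w in enumerate(vals)]
        assert compute_stats(resm, None).mean_writhe == pytest.approx(
            -compute_stats(res, None).mean_writhe
        )
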