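"""Limit-cycle exclusion, Lyapunov regions of attraction, separatrices, basins."""

import numpy as np
import pytest

from animfa import (
    ModelParameters,
    basin_map,
    builtin_pair,
    dulac_expression,
    estimate_region_of_attraction,
    lyapunov_matrix,
    pair_from_callables,
    polyline_side,
    separatrix,
    verify_no_limit_cycles,
)
from animfa.equilibria import all_equilibria
from animfa.global_analysis import integrate_lattice


class TestDulac:
    def test_point_value(self, params_super):
        val = dulac_expression((0.5, 0.5), params_super, builtin_pair("linear_breaking"))
        assert val == pytest.approx(-11.0)

    def test_reduces_to_minus_tau_where_creation_vanishes(self, params_super):
        # aid has f_cr(1) -> 0 along y -> 1; exactly zero creation at y where 2y(1-y)=0
        pair = pair_from_callables(lambda y: np.ones_like(y), lambda y: 0.0 * y)
        assert dulac_expression((0.3, 0.7), params_super, pair) == pytest.approx(-3.0)

    def test_boundary_is_domain_error(self, params_super):
        with pytest.raises(ValueError):
            dulac_expression((0.0, 0.5), params_super, builtin_pair("rlad"))

    def test_strictly_negative_for_builtins(self, params_super, any_pair):
        report = verify_no_limit_cycles(params_super, any_pair, grid=(201, 201))
        assert report.passed
        assert report.max_value < 0.0

    def test_asis_bounded_by_minus_tau(self, params_super):
        report = verify_no_limit_cycles(params_super, builtin_pair("asis"))
        assert report.max_value <= -params_super.tau

    def test_random_valid_pairs(self, params_super, rng):
        """Negativity holds for arbitrary non-negative responses, not just built-ins."""
        for _ in range(20):
            a, b, c = rng.uniform(-1.0, 1.0, size=3)
            d, e, f = rng.uniform(-1.0, 1.0, size=3)
            pair = pair_from_callables(
                lambda y, a=a, b=b, c=c: (a + b * y + c * y**2) ** 2,
                lambda y, d=d, e=e, f=f: (d + e * y + f * y**2) ** 2,
            )
            report = verify_no_limit_cycles(params_super, pair)
            assert report.passed


class TestLyapunov:
    def test_identity_jacobian(self):
        P = lyapunov_matrix(-np.eye(2))
        assert np.allclose(P, 0.5 * np.eye(2))

    def test_aid_dfe_matrix(self):
        P = lyapunov_matrix(np.array([[-1.0, 0.0], [2.0, -1.0]]))
        assert np.allclose(P, [[1.5, 0.5], [0.5, 0.5]], atol=1e-12)

    def test_defining_equation_for_random_stable_jacobians(self, rng):
        for _ in range(25):
            A = rng.normal(size=(2, 2))
            shift = max(np.real(np.linalg.eigvals(A)).max(), 0.0) + rng.uniform(0.1, 2.0)
            J = A - shift * np.eye(2)
            P = lyapunov_matrix(J)
            assert np.max(np.abs(P @ J + J.T @ P + np.eye(2))) <= 1e-12
            assert np.all(np.linalg.eigvalsh(P) > 0.0)

    def test_unstable_jacobian_rejected(self):
        with pytest.raises(ValueError, match="stable equilibrium"):
            lyapunov_matrix(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestRegionOfAttraction:
    def test_aid_dfe_region_nondegenerate_and_sound(self, params_super):
        pair = builtin_pair("aid")
        eqs = all_equilibria(params_super, pair)
        dfe = eqs[0]
        stable_ee = [e for e in eqs if e.kind == "endemic"
                     and e.stability == "stable_node"][0]
        roa = estimate_region_of_attraction(dfe, params_super, pair, grid=(101, 101))
        assert roa.c_star > 0.0
        pts = roa.omega_points()
        assert len(pts) > 100  # contains a neighbourhood of (0, 0)
        labels = integrate_lattice(
            pts[:, 0], pts[:, 1], params_super, pair, [dfe, stable_ee], horizon=500.0
        )
        assert np.all(labels == 0)  # inner estimate: every point flows to the DFE

    def test_negative_vdot_inside(self, params_super):
        pair = builtin_pair("aid")
        dfe = all_equilibria(params_super, pair)[0]
        roa = estimate_region_of_attraction(dfe, params_super, pair, grid=(101, 101))
        assert roa.vdot_max_inside < 0.0


class TestSeparatrix:
    def test_passes_through_interior_saddle(self, params_super):
        pair = builtin_pair("aid")
        saddle = [e for e in all_equilibria(params_super, pair)
                  if e.stability == "saddle"][0]
        assert (saddle.y, saddle.z) == pytest.approx((1.0 / 3.0, 0.5), abs=1e-10)
        curve = separatrix(saddle, params_super, pair)
        dist = np.min(np.hypot(curve[:, 0] - 1.0 / 3.0, curve[:, 1] - 0.5))
        assert dist <= 1e-5

    def test_sides_converge_to_different_attractors(self, params_super):
        pair = builtin_pair("aid")
        eqs = all_equilibria(params_super, pair)
        dfe = eqs[0]
        saddle = [e for e in eqs if e.stability == "saddle"][0]
        stable_ee = [e for e in eqs if e.stability == "stable_node"
                     and e.kind == "endemic"][0]
        curve = separatrix(saddle, params_super, pair)
        # normal offset at the saddle
        k = int(np.argmin(np.hypot(curve[:, 0] - saddle.y, curve[:, 1] - saddle.z)))
        tangent = curve[k + 1] - curve[k - 1]
        normal = np.array([-tangent[1], tangent[0]])
        normal /= np.linalg.norm(normal)
        probes = np.array([saddle.y, saddle.z]) + np.outer([1e-3, -1e-3], normal)
        labels = integrate_lattice(
            probes[:, 0], probes[:, 1], params_super, pair, [dfe, stable_ee],
            horizon=500.0,
        )
        assert sorted(labels) == [0, 1]

    def test_no_saddle_means_no_separatrix(self, params_super):
        pair = builtin_pair("linear_breaking")
        ee = [e for e in all_equilibria(params_super, pair) if e.kind == "endemic"][0]
        with pytest.raises(ValueError):
            separatrix(ee, params_super, pair)


class TestBasinMap:
    def test_bistable_aid(self, params_super):
        pair = builtin_pair("aid")
        bm = basin_map(params_super, pair, grid=(21, 21), horizon=500.0)
        assert len(bm.attractors) == 2
        gy, gz = bm.grid_y, bm.grid_z
        i_low = (np.abs(gy - 0.05).argmin(), np.abs(gz - 0.10).argmin())
        i_high = (np.abs(gy - 0.50).argmin(), np.abs(gz - 0.90).argmin())
        lab_low = bm.labels[i_low]
        lab_high = bm.labels[i_high]
        assert lab_low != lab_high
        assert bm.attractors[lab_low].kind == "dfe"
        assert bm.attractors[lab_high].kind == "endemic"
        assert bm.attractors[lab_high].y == pytest.approx(0.5, abs=1e-8)

    def test_monostable_linear_breaking(self, params_super):
        pair = builtin_pair("linear_breaking")
        bm = basin_map(params_super, pair, grid=(11, 11), horizon=500.0)
        interior = bm.labels[1:-1, 1:-1]
        ee_idx = [i for i, e in enumerate(bm.attractors) if e.kind == "endemic"][0]
        assert np.all(interior == ee_idx)

    def test_labels_match_separatrix_side(self, params_super):
        pair = builtin_pair("aid")
        eqs = all_equilibria(params_super, pair)
        saddle = [e for e in eqs if e.stability == "saddle"][0]
        curve = separatrix(saddle, params_super, pair)
        bm = basin_map(params_super, pair, grid=(31, 31), horizon=500.0)
        Y, Z = np.meshgrid(bm.grid_y, bm.grid_z, indexing="ij")
        pts = np.column_stack([Y.ravel(), Z.ravel()])
        side = polyline_side(curve, pts)
        lab = bm.labels.ravel()
        resolved = lab >= 0
        # each side of the curve should map to a single basin label
        agree = 0
        for s in (-1.0, 1.0):
            mask = resolved & (side == s)
            values, counts = np.unique(lab[mask], return_counts=True)
            agree += counts.max()
        assert agree / resolved.sum() >= 0.99
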