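"""Equilibria, Jacobians, stability labels, R0 and critical thresholds."""

import math

import numpy as np
import pytest

from animfa import (
    ModelParameters,
    NextGenerationNotApplicable,
    basic_reproduction_number,
    builtin_pair,
    classify_stability,
    closed_form_ee,
    critical_threshold,
    disease_free_equilibrium,
    endemic_equilibria,
    jacobian,
    pair_from_callables,
)
from animfa.dynamics import vector_field


class TestDiseaseFree:
    def test_linear_breaking_dfe(self, params_super):
        eq = disease_free_equilibrium(params_super, builtin_pair("linear_breaking"))
        assert (eq.y, eq.z) == (0.0, 1.0)
        assert eq.kind == "dfe"

    def test_aid_dfe_always_stable(self, params_super):
        eq = disease_free_equilibrium(params_super, builtin_pair("aid"))
        assert (eq.y, eq.z) == (0.0, 0.0)
        assert eq.stability == "stable_node"

    def test_rlad_dfe_link_density(self, params_super):
        eq = disease_free_equilibrium(params_super, builtin_pair("rlad"))
        assert eq.z == pytest.approx(0.5)  # 1/(1+omega) at omega=1

    def test_degenerate_family_when_both_responses_vanish(self, params_super):
        pair = pair_from_callables(lambda y: y, lambda y: y, name="both_vanish")
        eq = disease_free_equilibrium(params_super, pair)
        assert eq.kind == "dfe_family"
        assert eq.z_range == (0.0, 1.0)
        assert eq.stability == "undetermined"


class TestEndemic:
    @pytest.mark.parametrize(
        "name, expected_y",
        [
            ("linear_breaking", [0.5]),
            ("asis", [1.0 / 3.0]),
            ("aid", [1.0 / 3.0, 0.5]),
            ("rlad", [1.0 / 3.0]),
        ],
    )
    def test_supercritical_roots(self, params_super, name, expected_y):
        ees = endemic_equilibria(params_super, builtin_pair(name))
        assert [e.y for e in ees] == pytest.approx(expected_y, abs=1e-10)
        for e in ees:
            # link density consistent with the y-root
            assert e.z == pytest.approx(1.0 / (3.0 * (1.0 - e.y)), abs=1e-10)

    def test_subcritical_is_empty(self, params_sub):
        assert endemic_equilibria(params_sub, builtin_pair("linear_breaking")) == []

    def test_residuals_vanish(self, params_super, any_pair):
        for e in endemic_equilibria(params_super, any_pair):
            dy, dz = vector_field((e.y, e.z), params_super, any_pair)
            assert max(abs(dy), abs(dz)) <= 1e-10

    def test_existence_above_threshold_random_draws(self, rng):
        """R0 > 1 guarantees at least one endemic equilibrium."""
        for name in ("rlad", "linear_breaking", "asis"):
            pair = builtin_pair(name)
            found = 0
            trials = 0
            while found < 10 and trials < 200:
                trials += 1
                tau = rng.uniform(0.2, 10.0)
                zeta, xi = rng.uniform(0.2, 5.0, size=2)
                p = ModelParameters(tau=tau, zeta=zeta, xi=xi)
                if basic_reproduction_number(p, pair) <= 1.0:
                    continue
                found += 1
                assert endemic_equilibria(p, pair), (name, tau, zeta, xi)
            assert found == 10

    def test_near_fold_root_pair_recovered(self):
        """Two endemic roots closer than the scan spacing are still found."""
        omega = 1.0
        tau_star = (omega + 2.0 + math.sqrt(8.0 * omega)) / 2.0
        p = ModelParameters(tau=tau_star + 1e-7, zeta=1.0, xi=1.0)
        ees = endemic_equilibria(p, builtin_pair("aid"))
        expected = closed_form_ee("aid", p.tau, 1.0)
        assert len(ees) == len(expected) == 2
        for e, (ye, ze) in zip(ees, expected):
            assert e.y == pytest.approx(ye, abs=1e-8)


class TestJacobian:
    def test_lower_triangular_at_disease_free_boundary(self, params_super, any_pair):
        J = jacobian((0.0, 0.7), params_super, any_pair)
        assert J[0, 1] == 0.0

    def test_aid_dfe_matrix(self, params_super):
        J = jacobian((0.0, 0.0), params_super, builtin_pair("aid"))
        assert np.allclose(J, [[-1.0, 0.0], [2.0, -1.0]])

    def test_rlad_endemic_eigenvalues(self, params_super):
        ee = endemic_equilibria(params_super, builtin_pair("rlad"))[0]
        eigs = sorted(np.real(ee.eigenvalues))
        assert eigs == pytest.approx([-2.0, -0.5], abs=1e-10)


class TestClassification:
    @pytest.mark.parametrize(
        "eigs, label",
        [
            ((-0.5, -2.0), "stable_node"),
            ((-0.1 + 0.5j, -0.1 - 0.5j), "stable_spiral"),
            ((0.3, 1.0), "unstable_node"),
            ((0.2 + 1j, 0.2 - 1j), "unstable_spiral"),
            ((-1.0, 2.0), "saddle"),
            ((-1.0, 0.0), "undetermined"),
            ((-1.0, 5e-9), "undetermined"),
        ],
    )
    def test_labels(self, eigs, label):
        assert classify_stability(eigs, tol=1e-8) == label


class TestR0:
    def test_rlad(self, params_super):
        assert basic_reproduction_number(params_super, builtin_pair("rlad")) == pytest.approx(1.5)

    def test_linear_breaking(self, params_super):
        assert basic_reproduction_number(
            params_super, builtin_pair("linear_breaking")
        ) == pytest.approx(3.0)

    def test_asis(self, params_super):
        assert basic_reproduction_number(params_super, builtin_pair("asis")) == pytest.approx(3.0)

    def test_aid_not_applicable(self, params_super):
        with pytest.raises(NextGenerationNotApplicable):
            basic_reproduction_number(params_super, builtin_pair("aid"))

    def test_ee_coincides_with_dfe_at_threshold(self):
        """At R0 = 1 the endemic equilibrium merges into the disease-free one."""
        for name, tau_crit in (("rlad", 2.0), ("linear_breaking", 1.0)):
            p = ModelParameters(tau=tau_crit + 1e-9, zeta=1.0, xi=1.0)
            pair = builtin_pair(name)
            dfe = disease_free_equilibrium(p, pair)
            ees = endemic_equilibria(p, pair)
            if ees:
                assert np.hypot(ees[0].y - dfe.y, ees[0].z - dfe.z) <= 1e-6


class TestThreshold:
    def test_aid_fold(self):
        p = ModelParameters(tau=2.0, zeta=1.0, xi=1.0)
        th = critical_threshold(p, builtin_pair("aid"), (1.0, 5.0), tol=1e-7)
        assert th.tau_star == pytest.approx((3.0 + 2.0 * math.sqrt(2.0)) / 2.0, abs=1e-6)
        assert (th.ee_count_below, th.ee_count_above) == (0, 2)

    def test_linear_breaking_transcritical(self):
        p = ModelParameters(tau=1.0, zeta=1.0, xi=1.0)
        th = critical_threshold(p, builtin_pair("linear_breaking"), (0.5, 2.0), tol=1e-7)
        assert th.tau_star == pytest.approx(1.0, abs=1e-6)

    def test_rlad_threshold(self):
        p = ModelParameters(tau=1.0, zeta=1.0, xi=1.0)
        th = critical_threshold(p, builtin_pair("rlad"), (1.0, 3.0), tol=1e-7)
        assert th.tau_star == pytest.approx(2.0, abs=1e-6)

    def test_no_threshold_in_range(self):
        p = ModelParameters(tau=1.0, zeta=1.0, xi=1.0)
        with pytest.raises(ValueError, match="no threshold"):
            critical_threshold(p, builtin_pair("linear_breaking"), (2.0, 3.0))
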