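"""Discretization, derivative operators, analytic tail, and the full solve."""

import math

import numpy as np
import pytest

from lipid_edl import (
    GridError,
    HeadGroupSpec,
    SystemParams,
    analytic_tail,
    argmax_parabolic,
    discretize,
    fd_derivatives,
    gouy_chapman_counterions,
    gouy_chapman_salt,
    marginals,
    plane_charge_density,
    solve,
)
from lipid_edl.constants import FOUR_PI
from lipid_edl.solver import orientation_statistics

ROTOR = HeadGroupSpec(variant="rigid_rotor", l1=0.5, l2=0.5)


class TestDiscretize:
    def test_rotor_node_counts(self):
        g = discretize(ROTOR, 0.01)
        assert g.i_d2 == 50 and g.i_d1 == 100  # 51 nodes in R1, 50 more in R2
        assert g.x[g.i_d2] == pytest.approx(0.5)
        assert g.x[g.i_d1] == pytest.approx(1.0)

    def test_triangular_equal_arms_single_region(self):
        spec = HeadGroupSpec(
            variant="triangular", l1=0.68, l2=0.68, alpha=30.0, q1=-1, q2=-1
        )
        g = discretize(spec, 0.01)
        assert g.i_d2 is None  # R2 collapses
        assert g.d1 == g.d2 == 0.68

    def test_zwitterionic_single_region(self):
        g = discretize(HeadGroupSpec(variant="zwitterionic", l1=1.0), 0.01)
        assert g.i_d2 is None and g.d1 == 1.0

    def test_incommensurate_step_adjusted_down(self):
        g = discretize(ROTOR, 0.013)
        assert g.h <= 0.013
        assert round(g.d2 / g.h) * g.h == pytest.approx(g.d2)

    def test_too_coarse_rejected(self):
        with pytest.raises(GridError):
            discretize(ROTOR, 0.2)


class TestFdDerivatives:
    def test_constant_has_zero_derivatives(self):
        f = np.full(21, 3.7)
        d1, d2 = fd_derivatives(f, 0.01)
        assert np.max(np.abs(d1)) < 1e-10 and np.max(np.abs(d2)) < 1e-8

    def test_quadratic_is_exact(self):
        x = np.arange(0, 0.5001, 0.01)
        d1, d2 = fd_derivatives(x**2, 0.01)
        np.testing.assert_allclose(d2, 2.0, atol=1e-9)
        np.testing.assert_allclose(d1, 2 * x, atol=1e-10)

    def test_second_order_convergence_on_sine(self):
        errs = []
        for h in (0.02, 0.01, 0.005):
            x = np.arange(0, 1 + h / 2, h)
            _, d2 = fd_derivatives(np.sin(x), h)
            errs.append(np.max(np.abs(d2 + np.sin(x))))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.3)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.3)


class TestAnalyticTail:
    def _params_salt(self, c=0.1):
        return SystemParams(
            area_per_lipid=0.6,
            beta=0.5,
            electrolyte_mode="salt_1_1",
            bulk_concentration=c,
        )

    def test_zero_boundary_value_gives_flat_tail(self):
        tail = analytic_tail(0.0, "salt_1_1", self._params_salt(), d1=1.0)
        x = np.linspace(1.0, 10.0, 50)
        assert np.max(np.abs(tail.psi_at(x))) == 0.0
        assert tail.slope_d1 == 0.0

    def test_debye_hueckel_limit(self):
        p = self._params_salt()
        psi_d1 = -0.05
        tail = analytic_tail(psi_d1, "salt_1_1", p, d1=1.0)
        x = np.linspace(1.0, 4.0, 60)
        expected = psi_d1 * np.exp(-(x - 1.0) / p.debye_length)
        assert np.max(np.abs(tail.psi_at(x) - expected)) < 0.01 * abs(psi_d1)

    def test_counterion_tail_first_integral(self):
        p = SystemParams(area_per_lipid=0.6, beta=0.5)
        n_d1 = 0.3
        tail = analytic_tail(0.0, "counterions_only", p, n_d1=n_d1, d1=1.0)
        lb = p.bjerrum_length
        assert tail.slope_d1**2 == pytest.approx(8 * math.pi * lb * n_d1, rel=1e-12)
        # Gauss's law along the tail: psi'' = -4 pi lB n
        x = np.linspace(1.0, 6.0, 2001)
        d1_, d2_ = fd_derivatives(tail.psi_at(x), x[1] - x[0])
        np.testing.assert_allclose(
            d2_[1:-1], -FOUR_PI * lb * tail.n_at(x)[1:-1], rtol=1e-4
        )

    def test_uncharged_system_is_flat_vacuum(self):
        p = SystemParams(area_per_lipid=0.6, beta=1.0, nonstructured_charge=0.0)
        spec = HeadGroupSpec(variant="rigid_rotor", l1=0.5, l2=0.5, q0=0.0)
        sol = solve(p, spec, h=0.02)
        assert np.max(np.abs(sol.psi)) < 1e-10
        assert sol.converged


class TestSolve:
    def test_beta_one_reduces_to_gouy_chapman_salt(self):
        p = SystemParams(
            area_per_lipid=0.6,
            beta=1.0,
            electrolyte_mode="salt_1_1",
            bulk_concentration=0.1,
        )
        sol = solve(p, ROTOR, h=0.005)
        gc = gouy_chapman_salt(plane_charge_density(p, ROTOR), 0.1, p)
        x = np.linspace(0.0, 5 * p.debye_length, 200)
        dev = np.max(np.abs(sol.psi_at(x) - gc.psi_at(x)))
        assert dev / np.max(np.abs(gc.psi_at(x))) < 0.005

    def test_beta_one_reduces_to_gouy_counterions(self):
        p = SystemParams(area_per_lipid=0.6, beta=1.0)
        sol = solve(p, ROTOR, h=0.005)
        gc = gouy_chapman_counterions(plane_charge_density(p, ROTOR), p)
        x = sol.x
        n_gc = gc.n_plus_at(x)
        assert np.max(np.abs(sol.n_plus() - n_gc) / n_gc) < 0.005

    def test_counterion_bump_near_terminal_charge(self, rotor_ct_l1):
        """High-charge rotor: the counterion decay has a local plateau in the
        terminal-charge region (l1, l1+l2), and psi rises monotonically."""
        sol = rotor_ct_l1
        x, n = sol.x, sol.n_plus()
        dn = np.gradient(n, x)
        assert np.all(np.diff(sol.psi) >= -1e-12)
        assert np.all(dn <= 1e-12)  # density itself still decreases
        interior = (x > sol.spec.l1 * 0.9) & (x < sol.grid.d1)
        i = np.arange(len(x))[interior]
        has_local_max = any(
            dn[j] > dn[j - 1] and dn[j] >= dn[j + 1] for j in i[1:-1]
        )
        assert has_local_max

    def test_rotor_salt_orientation_maximum(self, rotor_salt_l1):
        am = argmax_parabolic(rotor_salt_l1.W.x, rotor_salt_l1.W.W)
        assert am == pytest.approx(0.22, abs=0.03)

    def test_flexible_terminal_marginal_peak(self, flexible_salt):
        (_, _), (s, Ws) = marginals(flexible_salt.W)
        assert argmax_parabolic(s, Ws) == pytest.approx(0.5, abs=0.03)

    def test_low_charge_monotonicity(self):
        p = SystemParams(area_per_lipid=6.0, beta=0.5)
        sol = solve(p, HeadGroupSpec(variant="rigid_rotor", l1=1.0, l2=1.0), h=0.01)
        assert np.all(np.diff(sol.psi) >= -1e-12)
        assert np.all(np.diff(sol.W.W) >= -1e-10)

    def test_non_convergence_reported_not_raised(self):
        p = SystemParams(area_per_lipid=0.6, beta=0.5)
        sol = solve(p, ROTOR, h=0.02, max_iter=1)
        assert not sol.converged
        assert sol.residual_norm > 0


class TestSolutionInvariants:
    @pytest.mark.parametrize(
        "fixture",
        [
            "rotor_salt_l1",
            "rotor_salt_l05",
            "rotor_ct_l1",
            "flexible_ct",
            "flexible_salt",
            "triangular_ct",
        ],
    )
    def test_electroneutrality(self, fixture, request):
        sol = request.getfixturevalue(fixture)
        assert sol.converged
        assert abs(sol.electroneutrality_residual()) < 1e-6

    @pytest.mark.parametrize("fixture", ["rotor_salt_l1", "rotor_ct_l1"])
    def test_c1_continuity_at_d2(self, fixture, request):
        sol = request.getfixturevalue(fixture)
        scale = np.max(np.abs(np.diff(sol.psi))) / sol.grid.h
        assert sol.c1_jump() < 0.01 * scale

    def test_positive_ion_densities(self, rotor_salt_l1):
        assert np.all(rotor_salt_l1.n_plus() > 0)
        assert np.all(rotor_salt_l1.n_minus() > 0)

    def test_grid_convergence_order(self):
        p = SystemParams(
            area_per_lipid=0.6,
            beta=0.5,
            electrolyte_mode="salt_1_1",
            bulk_concentration=0.1,
        )
        sols = {h: solve(p, ROTOR, h=h) for h in (0.02, 0.01, 0.005)}
        xc = sols[0.02].x
        e1 = np.max(np.abs(sols[0.02].psi - sols[0.01].psi_at(xc)))
        e2 = np.max(np.abs(sols[0.01].psi_at(xc) - sols[0.005].psi_at(xc)))
        assert math.log2(e1 / e2) >= 1.8

    def test_salt_to_counterion_limit(self):
        """At c -> 0 the salt solution approaches the counterions-only
        profile on [0, d1] (compared gauge-free, relative to psi(d1))."""
        p_ct = SystemParams(area_per_lipid=0.6, beta=0.5)
        p_lo = SystemParams(
            area_per_lipid=0.6,
            beta=0.5,
            electrolyte_mode="salt_1_1",
            bulk_concentration=1e-5,
        )
        s_ct = solve(p_ct, ROTOR, h=0.005)
        s_lo = solve(p_lo, ROTOR, h=0.005)
        delta = (s_lo.psi - s_lo.psi[-1]) - s_ct.psi
        assert np.max(np.abs(delta)) / np.max(np.abs(s_ct.psi)) < 0.01

    def test_de_broglie_gauge_invariance(self):
        sols = [
            solve(
                SystemParams(area_per_lipid=0.6, beta=0.5, de_broglie=v),
                ROTOR,
                h=0.01,
            )
            for v in (1.0, 137.0)
        ]
        np.testing.assert_array_equal(sols[0].psi, sols[1].psi)
        np.testing.assert_array_equal(sols[0].n_plus(), sols[1].n_plus())


class TestMarginals:
    def test_separable_density_recovers_factors(self):
        # direct check of the quadrature-measure marginalization on a
        # synthetic separable density over the flexible support
        p = SystemParams(area_per_lipid=0.6, beta=0.5)
        spec = HeadGroupSpec(variant="flexible", l1=0.5, l2=0.5)
        sol = solve(p, spec, h=0.01)
        (x, Wx), (s, Ws) = marginals(sol.W)
        V = sol.W.measure2d
        # W2d marginalized with the same measure reproduces Wx, Ws
        mass_x = (V * sol.W.W2d).sum(axis=1)
        wx = np.full(len(x), 0.01)
        wx[0] = wx[-1] = 0.005
        np.testing.assert_allclose(mass_x / wx, Wx, rtol=1e-10)
        assert abs(np.trapezoid(Wx, x) - 1) < 1e-8
        assert abs(np.trapezoid(Ws, s) - 1) < 1e-8

    def test_ridge_density_shifts_marginal(self):
        """If W concentrates on the stretched ridge s = x + l2, the terminal
        marginal is the middle marginal shifted by l2."""
        p = SystemParams(area_per_lipid=6.0, beta=0.5)
        # strong stretching: highly charged terminal, neutral middle
        spec = HeadGroupSpec(variant="flexible", l1=0.5, l2=0.5, q1=0.0, q2=-3.0)
        sol = solve(p, spec, h=0.005)
        (x, Wx), (s, Ws) = marginals(sol.W)
        stats_x = orientation_statistics(x, Wx)
        stats_s = orientation_statistics(s, Ws)
        assert stats_s["mode"] > stats_x["mode"]
        assert stats_s["mean"] > stats_x["mean"] + 0.3 * spec.l2

    def test_marginals_require_flexible(self, rotor_salt_l05):
        with pytest.raises(ValueError):
            marginals(rotor_salt_l05.W)


class TestArgmaxParabolic:
    def test_exact_on_parabola(self):
        x = np.linspace(0, 1, 21)
        y = -((x - 0.437) ** 2)
        assert argmax_parabolic(x, y) == pytest.approx(0.437, abs=1e-12)

    def test_boundary_maximum_returns_node(self):
        x = np.linspace(0, 1, 11)
        assert argmax_parabolic(x, x) == 1.0
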