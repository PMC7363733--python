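"""Saddle linearisation, heteroclinic branch, WKB potential and prefactor."""

import numpy as np
import pytest

import burstwkb as bw
from burstwkb.operators import dA_dtheta
from burstwkb.qss import qss_distribution


class TestSaddleLinearization:
    def test_mixed_derivative_matches_rate_equation_slope(self, pos_fb_fig4, fig4_fps):
        """H_xtheta(x_*, 0) = <B> fbar'(x_*) - 1, which is also the x-derivative
        of H_theta(x, 0) by finite differences."""
        h = 1e-6
        for fp in fig4_fps:
            sd = bw.saddle_linearization(pos_fb_fig4, fp)
            expected = (
                pos_fb_fig4.burst.mean
                * bw.effective_rate_derivative(pos_fb_fig4, fp.x_star)
                - 1.0
            )
            assert sd.H_xtheta == pytest.approx(expected, rel=1e-12)
            fd = (
                bw.rate_rhs(pos_fb_fig4, fp.x_star + h)
                - bw.rate_rhs(pos_fb_fig4, fp.x_star - h)
            ) / (2 * h)
            assert sd.H_xtheta == pytest.approx(fd, abs=1e-6)

    def test_second_theta_derivative_matches_finite_difference(
        self, pos_fb_fig4, fig4_fps
    ):
        h = 1e-3
        for fp in fig4_fps:
            sd = bw.saddle_linearization(pos_fb_fig4, fp)
            fd = (
                bw.hamiltonian(pos_fb_fig4, fp.x_star, h)
                - 2 * bw.hamiltonian(pos_fb_fig4, fp.x_star, 0.0)
                + bw.hamiltonian(pos_fb_fig4, fp.x_star, -h)
            ) / h**2
            assert sd.H_thetatheta == pytest.approx(fd, rel=1e-4)

    def test_gauge_invariance_of_second_derivative(self, pos_fb_fig4, fig4_fps):
        """H_thetatheta is unchanged under vtilde -> vtilde + c rho(x_*)."""
        fp = fig4_fps[0]
        sd = bw.saddle_linearization(pos_fb_fig4, fp)
        rho = qss_distribution(pos_fb_fig4, fp.x_star).rho
        dath = dA_dtheta(pos_fb_fig4, fp.x_star, 0.0)
        base = fp.x_star * (
            1.0 + pos_fb_fig4.burst.second_moment / pos_fb_fig4.burst.mean
        )
        for c in (-1.0, 1.0, 10.0):
            shifted = base + 2.0 * float((dath @ (sd.v_tilde + c * rho)).sum())
            assert shifted == pytest.approx(sd.H_thetatheta, abs=1e-9)

    def test_saddle_slopes_have_lyapunov_signs(self, fig4_branch):
        """Phi'' > 0 at stable fixed points, < 0 at the unstable one."""
        signs = [np.sign(sd.slope) for sd in fig4_branch.saddles]
        assert signs == [1.0, -1.0, 1.0]


class TestBranch:
    def test_theta_vanishes_exactly_at_fixed_points(self, fig4_branch):
        for fp, i in zip(fig4_branch.fixed_points, fig4_branch.fp_indices):
            assert fig4_branch.grid[i] == fp.x_star
            assert fig4_branch.theta[i] == 0.0

    def test_branch_lies_on_zero_level_set(self, pos_fb_fig4, fig4_branch):
        hs = [
            bw.hamiltonian(pos_fb_fig4, x, th)
            for x, th in zip(fig4_branch.grid[::25], fig4_branch.theta[::25])
        ]
        assert max(abs(h) for h in hs) < 1e-6

    def test_theta_opposes_deterministic_flow(self, pos_fb_fig4, fig4_branch):
        fps = np.array([fp.x_star for fp in fig4_branch.fixed_points])
        rhs = np.array([bw.rate_rhs(pos_fb_fig4, x) for x in fig4_branch.grid])
        off = np.abs(fig4_branch.grid[:, None] - fps[None, :]).min(axis=1) > 1e-9
        assert np.all((fig4_branch.theta * rhs)[off] < 0)

    def test_branch_slope_at_saddles_matches_linearisation(self, fig4_branch):
        for sd, i in zip(fig4_branch.saddles, fig4_branch.fp_indices):
            fd = (fig4_branch.theta[i + 1] - fig4_branch.theta[i - 1]) / (
                fig4_branch.grid[i + 1] - fig4_branch.grid[i - 1]
            )
            assert fd == pytest.approx(sd.slope, rel=0.01)


class TestPotential:
    def test_monostable_potential_is_single_well(self, fig3_branch):
        i0 = fig3_branch.fp_indices[0]
        phi = fig3_branch.phi
        assert np.all(np.diff(phi[: i0 + 1]) <= 0)
        assert np.all(np.diff(phi[i0:]) >= 0)
        assert phi[i0] == 0.0

    def test_extrema_at_fixed_points(self, fig4_branch):
        phi = fig4_branch.phi
        i_m, i_0, i_p = fig4_branch.fp_indices
        assert phi[i_0] > phi[i_m] > phi[i_p] == 0.0  # right well deeper here
        # local extrema: neighbours on the correct side
        for i, sd in zip(fig4_branch.fp_indices, fig4_branch.saddles):
            sign = 1.0 if sd.slope > 0 else -1.0
            assert sign * (phi[i + 1] - phi[i]) > 0
            assert sign * (phi[i - 1] - phi[i]) > 0

    def test_burstiness_flattens_the_potential(self):
        """Same rate equation, burstier production -> shallower wells:
        (<B>=4, rates/4) has strictly smaller well depths than (<B>=1, rates)."""

        def depths(mean, a0, a1):
            model = bw.ModelSpec(
                bw.make_burst_distribution(mean, 0),
                bw.make_step_response(20, 6, a0, a1),
                s_max=20,
                epsilon=0.1,
            )
            fps = bw.find_fixed_points(model)
            br = bw.potential(bw.trace_branch(model, fps, n_grid=801))
            phi = {fp.role: br.phi_at(fp.x_star) for fp in fps}
            return (
                phi["x_zero"] - phi["x_minus"],
                phi["x_zero"] - phi["x_plus"],
            )

        ref = depths(1, 2.0, 10.0)
        bursty = depths(4, 0.5, 2.5)
        assert bursty[0] < ref[0] and bursty[1] < ref[1]


class TestPrefactor:
    def test_prefactor_positive_and_anchored(self, fig4_branch):
        k = fig4_branch.prefactor
        assert np.all(k > 0)
        anchor = fig4_branch.fp_indices[0]
        assert k[anchor] == pytest.approx(1.0)

    def test_solvability_residual(self, pos_fb_fig4, fig4_branch):
        """The computed k satisfies k' sum(l alpha) + k sum(l beta) = 0 away
        from the fixed points."""
        x = fig4_branch.grid
        k = fig4_branch.prefactor
        g = fig4_branch.integrand
        kp = np.gradient(k, x)
        h_theta = np.array(
            [
                bw.grad_hamiltonian(pos_fb_fig4, xi, ti)[1]
                for xi, ti in zip(x, fig4_branch.theta)
            ]
        )
        num = g * h_theta
        resid = np.abs(kp * h_theta + k * num)
        scale = np.abs(k * num).max()
        fps = np.array([fp.x_star for fp in fig4_branch.fixed_points])
        interior = (x > x[0] + 0.2) & (x < x[-1] - 0.2)
        away = np.abs(x[:, None] - fps[None, :]).min(axis=1) > 0.1
        assert (resid[interior & away] / scale).max() < 1e-3

    def test_denominator_equals_h_theta_on_branch(self, pos_fb_fig4, fig4_branch):
        """sum_s l_s alpha_s = H_theta(x, theta(x)) since alpha = (dA/dtheta) w."""
        idx = np.arange(0, fig4_branch.grid.size, 100)
        for i in idx:
            x, th = fig4_branch.grid[i], fig4_branch.theta[i]
            dath = dA_dtheta(pos_fb_fig4, x, th)
            lhs = float(fig4_branch.l[i] @ (dath @ fig4_branch.w[i]))
            _, h_t = bw.grad_hamiltonian(pos_fb_fig4, x, th)
            assert lhs == pytest.approx(h_t, abs=1e-6)


class TestConditionalDistribution:
    def test_equals_qss_at_critical_points(self, pos_fb_fig4, fig4_branch):
        for fp in fig4_branch.fixed_points:
            w = bw.conditional_distribution(fig4_branch, fp.x_star)
            rho = qss_distribution(pos_fb_fig4, fp.x_star).rho
            assert np.abs(w - rho).max() < 1e-6

    def test_differs_from_qss_away_from_critical_points(
        self, pos_fb_fig4, fig4_branch
    ):
        x = 0.5 * (
            fig4_branch.fixed_points[0].x_star + fig4_branch.fixed_points[1].x_star
        )
        w = bw.conditional_distribution(fig4_branch, x)
        rho = qss_distribution(pos_fb_fig4, x).rho
        assert w.sum() == pytest.approx(1.0)
        assert 0.5 * np.abs(w - rho).sum() > 1e-3

    def test_outside_grid_raises(self, fig4_branch):
        with pytest.raises(ValueError):
            bw.conditional_distribution(fig4_branch, fig4_branch.grid[-1] + 1.0)
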