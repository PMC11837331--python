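"""Phase averaging, the three budget terms and the assembled lift estimate."""

import numpy as np
import pytest

from flapperoo.control_volume import (ControlVolumeSpec, FieldSeries,
                                      acceleration_term, clap_peak,
                                      lift_budget, momentum_flux_term,
                                      phase_average, pressure_term,
                                      uniform_freestream_fields)
from flapperoo.control_volume import _edge_pressure, _phase_derivative
from flapperoo.synthetic import (SyntheticSpec, default_jet_cv,
                                 jet_field_series, jet_truth_budget,
                                 make_jet_fields)

RHO = 1.2


def small_grid():
    x = np.linspace(-0.3, 0.3, 61)
    z = np.linspace(-0.2, 0.2, 41)
    return x, z


def make_fields(u, w, x, z, u_inf=4.0, f=3.0, **kw):
    return FieldSeries(x=x, z=z, u=u, w=w, freestream=u_inf, frequency=f,
                       **kw)


CV = ControlVolumeSpec(-0.15, 0.15, -0.12, 0.12)


class TestPhaseAverage:
    def test_stationary_field(self):
        x, z = small_grid()
        u0 = np.random.default_rng(0).normal(4.0, 0.5, (z.size, x.size))
        snaps = ((t, u0, 0.1 * u0) for t in np.arange(200) / 100.0)
        fields = phase_average(snaps, f=1.0, x=x, z=z, freestream=4.0,
                               n_bins=10)
        for b in range(10):
            np.testing.assert_allclose(fields.u[b], u0, rtol=1e-12)
            np.testing.assert_allclose(fields.w[b], 0.1 * u0, rtol=1e-12)
        np.testing.assert_allclose(fields.u_var, 0.0, atol=1e-12)

    def test_sinusoid_bin_means_match_analytic_bin_average(self):
        """Bin means of A sin(2 pi f t) equal the exact in-bin integral."""
        x = np.linspace(0, 0.1, 3)
        z = np.linspace(0, 0.1, 3)
        f, fs, n_bins, n_cyc, amp = 3.0, 500.0, 83, 40, 2.0
        n = int(fs * n_cyc / f)
        times = np.arange(n) / fs
        ones = np.ones((z.size, x.size))
        snaps = ((t, 4.0 * ones, amp * np.sin(2 * np.pi * f * t) * ones)
                 for t in times)
        fields = phase_average(snaps, f=f, x=x, z=z, freestream=4.0,
                               n_bins=n_bins)
        edges = np.arange(n_bins + 1) / n_bins
        exact = amp * (np.cos(2 * np.pi * edges[:-1])
                       - np.cos(2 * np.pi * edges[1:])) / (
            2 * np.pi / n_bins)
        # sampling at 500 Hz leaves ~2 samples/bin: allow the sampling bias
        np.testing.assert_allclose(fields.w[:, 0, 0], exact, atol=0.08)

    def test_empty_bin_reported_by_index(self):
        x, z = small_grid()
        ones = np.ones((z.size, x.size))
        snaps = [(0.01, ones, ones)]      # single snapshot -> one bin filled
        with pytest.raises(ValueError, match="empty phase bins"):
            phase_average(snaps, f=1.0, x=x, z=z, freestream=4.0, n_bins=5)


class TestAcceleration:
    def test_steady_field_gives_zero(self):
        fields = uniform_freestream_fields(n_bins=11, x=small_grid()[0],
                                           z=small_grid()[1])
        np.testing.assert_allclose(acceleration_term(fields, CV, RHO), 0.0,
                                   atol=1e-12)

    def test_linear_ramp_exact(self):
        """Uniform w = a t over area A_cv gives -rho a A_cv (reaction sign).

        The order-2 filter differentiates a linear ramp exactly; only
        interior bins are checked because the ramp is aperiodic while the
        phase derivative wraps.
        """
        x, z = small_grid()
        n_bins, f, a = 21, 3.0, 2.0
        t = (np.arange(n_bins) + 0.5) / (n_bins * f)
        w = a * t[:, None, None] * np.ones((1, z.size, x.size))
        u = np.full_like(w, 4.0)
        fields = make_fields(u, w, x, z)
        accel = acceleration_term(fields, CV, RHO)
        area = (CV.x_max - CV.x_min) * (CV.z_max - CV.z_min)
        np.testing.assert_allclose(accel[3:-3], -RHO * a * area, rtol=1e-9)

    def test_gaussian_pulse_matches_fine_central_difference(self):
        """At 10x phase resolution the SG derivative tracks the pulse <1%."""
        spec = SyntheticSpec(seed=0)
        fields = jet_field_series(spec, n_bins=830)
        cv = default_jet_cv(spec)
        accel = acceleration_term(fields, cv, RHO)
        # independent oracle: central difference of the momentum integral
        zs, xs = cv.indices(fields)
        integral = np.trapezoid(np.trapezoid(fields.w[:, zs, xs],
                                             dx=fields.dx, axis=2),
                                dx=fields.dz, axis=1)
        dt = fields.dt_phase
        oracle = -RHO * (np.roll(integral, -1) - np.roll(integral, 1)) / (
            2 * dt)
        scale = np.max(np.abs(oracle))
        np.testing.assert_allclose(accel, oracle, atol=0.01 * scale)

    def test_cv_outside_grid_rejected(self):
        fields = uniform_freestream_fields(n_bins=7, x=small_grid()[0],
                                           z=small_grid()[1])
        bad = ControlVolumeSpec(-1.0, 0.1, -0.1, 0.1)
        with pytest.raises(ValueError, match="outside"):
            acceleration_term(fields, bad, RHO)


class TestMomentumFlux:
    def test_uniform_freestream_zero(self):
        fields = uniform_freestream_fields(n_bins=7, x=small_grid()[0],
                                           z=small_grid()[1])
        np.testing.assert_allclose(momentum_flux_term(fields, CV, RHO), 0.0,
                                   atol=1e-12)

    def test_downward_outflow_through_bottom(self):
        """w = -W on the bottom edge only: flux term = +rho W^2 l."""
        x, z = small_grid()
        w_speed = 1.5
        w = np.zeros((5, z.size, x.size))
        iz0 = int(np.argmin(np.abs(z - CV.z_min)))
        w[:, :iz0 + 1, :] = -w_speed
        u = np.zeros_like(w)
        fields = make_fields(u, w, x, z)
        ell = CV.x_max - CV.x_min
        np.testing.assert_allclose(momentum_flux_term(fields, CV, RHO),
                                   RHO * w_speed**2 * ell, rtol=1e-9)

    def test_jet_flux_matches_fine_quadrature(self):
        """Edge trapezoids vs 4x-resolution quadrature of the same field."""
        spec = SyntheticSpec(seed=0)
        # tight, asymmetric CV so the Gaussian tails cross the boundary and
        # opposite edges do not cancel by symmetry; corners lie on grid
        # lines of both resolutions so the same rectangle is integrated
        cv = ControlVolumeSpec(-0.050, 0.080, -0.060, 0.120)
        fields = jet_field_series(spec, n_bins=83)
        coarse = momentum_flux_term(fields, cv, RHO)
        x0, x1, dx = spec.x_grid
        z0, z1, dz = spec.z_grid
        x_f = np.arange(x0, x1 + dx / 8, dx / 4)
        z_f = np.arange(z0, z1 + dz / 8, dz / 4)
        fine = momentum_flux_term(jet_field_series(spec, 83, x=x_f, z=z_f),
                                  cv, RHO)
        scale = np.max(np.abs(fine))
        np.testing.assert_allclose(coarse, fine, atol=0.01 * scale)


class TestPressure:
    def test_uniform_freestream_zero_both_methods(self):
        fields = uniform_freestream_fields(n_bins=7, x=small_grid()[0],
                                           z=small_grid()[1])
        for method in ("momentum_integration", "unsteady_bernoulli"):
            np.testing.assert_allclose(
                pressure_term(fields, CV, method=method, rho=RHO), 0.0,
                atol=1e-9)

    def test_steady_potential_flow_matches_bernoulli(self):
        """Edge pressure from momentum integration equals the Bernoulli
        closed form for a steady source-perturbed freestream."""
        x = np.linspace(-0.3, 0.3, 241)
        z = np.linspace(-0.2, 0.2, 161)
        xx, zz = np.meshgrid(x, z - 0.45)     # source well above the domain
        m, u_inf = 0.02, 4.0
        r2 = xx**2 + zz**2
        u = u_inf + m * xx / r2
        w = m * zz / r2
        n_bins = 7
        fields = make_fields(np.repeat(u[None], n_bins, 0),
                             np.repeat(w[None], n_bins, 0), x, z,
                             u_inf=u_inf)
        cv = ControlVolumeSpec(-0.2, 0.2, -0.1, 0.1)
        zs, xs = cv.indices(fields)
        iz0 = np.arange(z.size)[zs][0]
        du_dt = np.zeros_like(fields.u)
        for method in ("momentum_integration", "unsteady_bernoulli"):
            p = _edge_pressure(fields, zs, xs, iz0, du_dt, RHO, method)[0]
            speed2 = (u**2 + w**2)[iz0, xs]
            bernoulli = 0.5 * RHO * (speed2[0] - speed2)
            scale = np.max(np.abs(bernoulli))
            np.testing.assert_allclose(p, bernoulli, atol=0.01 * scale)

    def test_methods_agree_on_jet(self):
        spec = SyntheticSpec(seed=0)
        fields = jet_field_series(spec, n_bins=83)
        cv = default_jet_cv(spec, margin=2.0)
        p_mom = pressure_term(fields, cv, "momentum_integration", RHO)
        p_bern = pressure_term(fields, cv, "unsteady_bernoulli", RHO)
        budget = lift_budget(fields, cv, rho=RHO)
        scale = np.max(np.abs(budget.total))
        np.testing.assert_allclose(p_mom, p_bern, atol=0.05 * scale)

    def test_unknown_method_rejected(self):
        fields = uniform_freestream_fields(n_bins=7, x=small_grid()[0],
                                           z=small_grid()[1])
        with pytest.raises(ValueError, match="method"):
            pressure_term(fields, CV, method="poisson")


class TestLiftBudget:
    def test_uniform_freestream_null(self):
        fields = uniform_freestream_fields(n_bins=83)
        budget = lift_budget(fields, ControlVolumeSpec(-0.15, 0.15, -0.15,
                                                       0.15), rho=RHO)
        assert np.max(np.abs(budget.CL)) < 1e-12

    def test_budget_identity_exact(self):
        spec = SyntheticSpec(seed=0)
        budget = lift_budget(jet_field_series(spec, 83),
                             default_jet_cv(spec), rho=RHO)
        np.testing.assert_array_equal(
            budget.total, budget.accel + budget.momentum + budget.pressure)

    def test_jet_peak_matches_generator_truth(self):
        spec = SyntheticSpec(seed=0)
        cv = default_jet_cv(spec)
        budget = lift_budget(jet_field_series(spec, 83), cv, rho=RHO)
        truth = jet_truth_budget(spec, cv, np.linspace(0, 1, 4001))
        peak, _ = clap_peak(budget.phase, budget.CL)
        peak_truth, _ = clap_peak(truth["tau"], truth["CL"])
        assert peak == pytest.approx(peak_truth, rel=0.05)

    def test_cv_independence_over_nested_rectangles(self):
        spec = SyntheticSpec(seed=0)
        fields = jet_field_series(spec, 83)
        peaks = [clap_peak(*(lambda b: (b.phase, b.CL))(
            lift_budget(fields, default_jet_cv(spec, margin=m), rho=RHO)))[0]
            for m in (3.0, 3.5, 4.0)]
        assert (max(peaks) - min(peaks)) / max(peaks) < 0.05

    def test_galilean_shift_of_streamwise_velocity(self):
        spec = SyntheticSpec(seed=0)
        fields = jet_field_series(spec, 83)
        cv = default_jet_cv(spec)
        peak0, _ = clap_peak(*(lambda b: (b.phase, b.CL))(
            lift_budget(fields, cv, rho=RHO)))
        fields.u = fields.u + 1.0
        peak1, _ = clap_peak(*(lambda b: (b.phase, b.CL))(
            lift_budget(fields, cv, rho=RHO)))
        assert abs(peak1 - peak0) / peak0 < 0.02

    def test_grid_refinement_first_order_convergence(self):
        """Spatial error vs a 4x-fine reference at least halves with h."""
        spec = SyntheticSpec(seed=0)
        cv = default_jet_cv(spec)

        def total_at(step_div):
            x0, x1, dx = spec.x_grid
            z0, z1, dz = spec.z_grid
            x = np.arange(x0, x1 + dx / (2 * step_div), dx / step_div)
            z = np.arange(z0, z1 + dz / (2 * step_div), dz / step_div)
            return lift_budget(jet_field_series(spec, 83, x=x, z=z), cv,
                               rho=RHO).total

        ref = total_at(4)
        err1 = np.max(np.abs(total_at(1) - ref))
        err2 = np.max(np.abs(total_at(2) - ref))
        assert err2 <= err1 / 1.8

    def test_turbulent_flux_zero_without_variance(self):
        fields = uniform_freestream_fields(n_bins=7)
        budget = lift_budget(fields, ControlVolumeSpec(-0.15, 0.15, -0.15,
                                                       0.15), rho=RHO)
        np.testing.assert_array_equal(budget.turbulent_flux, 0.0)

    def test_turbulent_flux_reported_not_added(self):
        fields = uniform_freestream_fields(n_bins=7)
        fields.w_var = 0.04 * np.ones_like(fields.w)
        fields.uw_cov = np.zeros_like(fields.w)
        cv = ControlVolumeSpec(-0.15, 0.15, -0.15, 0.15)
        budget = lift_budget(fields, cv, rho=RHO)
        # uniform variance: bottom and top contributions cancel exactly
        np.testing.assert_allclose(budget.turbulent_flux, 0.0, atol=1e-12)
        np.testing.assert_array_equal(
            budget.total, budget.accel + budget.momentum + budget.pressure)

    def test_snapshot_pipeline_consistent_with_direct_fields(self):
        """Noise-free snapshots phase-averaged over whole cycles reproduce
        the analytic bin-centre field to within the bin-averaging bias."""
        spec = SyntheticSpec(seed=0, n_cycles=4, velocity_noise=0.0)
        fields = phase_average(make_jet_fields(spec), spec.frequency,
                               *spec.grids(), freestream=spec.freestream,
                               n_bins=83)
        direct = jet_field_series(spec, 83)
        assert np.max(np.abs(fields.w - direct.w)) < 0.05 * np.max(
            np.abs(direct.w))


class TestClapPeak:
    def test_zero_series(self):
        phase = np.linspace(0, 1, 83, endpoint=False)
        assert clap_peak(phase, np.zeros(83)) == (0.0, pytest.approx(0.7,
                                                                     abs=0.2))

    def test_gaussian_bump(self):
        phase = (np.arange(83) + 0.5) / 83
        h = 0.9
        cl = h * np.exp(-(phase - 0.8)**2 / (2 * 0.03**2))
        peak, at = clap_peak(phase, cl)
        assert peak == pytest.approx(h, rel=1e-3)
        assert at == pytest.approx(0.8, abs=0.01)

    def test_window_semantics_with_larger_outside_peak(self):
        phase = (np.arange(83) + 0.5) / 83
        cl = 2.0 * np.exp(-(phase - 0.3)**2 / (2 * 0.03**2)) \
            + 1.0 * np.exp(-(phase - 0.8)**2 / (2 * 0.03**2))
        peak, at = clap_peak(phase, cl)
        assert peak == pytest.approx(1.0, rel=1e-2)
        assert 0.7 <= at <= 0.9

    def test_empty_window_rejected(self):
        phase = (np.arange(83) + 0.5) / 83
        with pytest.raises(ValueError, match="window"):
            clap_peak(phase, np.zeros(83), window=(0.85, 0.851))
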