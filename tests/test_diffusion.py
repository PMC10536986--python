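"""MSD analysis and the finite-size (periodic Saffman-Delbrueck) fit."""

import numpy as np
import pytest

from cholbench import (
    MembraneGeometry,
    MSDCurve,
    PlanarTrajectorySet,
    compute_msd,
    dpbc_model,
    fit_finite_size,
    fit_msd_linear,
    mc_error_propagation,
    saffman_delbrueck_length,
)
from cholbench.diffusion import XI_SQUARE_LATTICE
from cholbench.observables import FiniteSizeSeries, ValidationError
from cholbench.synthetic import gen_brownian_traj, gen_finite_size_series


class TestComputeMSD:
    def test_pure_drift_is_annihilated(self):
        traj, _ = gen_brownian_traj(0.0, 16, 100, 1.0, leaflet_drift=0.5, seed=0)
        msd = compute_msd(traj)
        np.testing.assert_allclose(msd.msd, 0.0, atol=1e-20)

    def test_single_immobile_particle(self):
        times = np.arange(10.0)
        pos = np.zeros((2, 10, 2))
        traj = PlanarTrajectorySet(times, pos, np.array(["upper", "lower"]))
        assert compute_msd(traj).msd.max() == 0.0

    def test_invariant_under_rigid_translation(self, rng):
        traj, _ = gen_brownian_traj(3.0, 32, 200, 1.0, seed=5)
        ref = compute_msd(traj).msd
        shift = rng.normal(0, 5.0, (1, len(traj.times), 2))
        shifted = PlanarTrajectorySet(
            traj.times, traj.positions + shift, traj.leaflet
        )
        np.testing.assert_allclose(compute_msd(shifted).msd, ref, atol=1e-8)

    def test_matches_brute_force_on_tiny_trajectory(self, rng):
        pos = rng.standard_normal((3, 25, 2)).cumsum(axis=1)
        traj = PlanarTrajectorySet(
            np.arange(25.0), pos, np.array(["upper", "upper", "lower"])
        )
        msd = compute_msd(traj)
        p = pos.copy()
        for lab in ("upper", "lower"):
            m = traj.leaflet == lab
            drift = p[m].mean(axis=0) - p[m, 0, :].mean(axis=0)
            p[m] -= drift[None, :, :]
        brute = np.array(
            [
                np.mean(np.sum((p[:, d:, :] - p[:, : 25 - d, :]) ** 2, axis=2))
                if d else 0.0
                for d in range(25)
            ]
        )
        np.testing.assert_allclose(msd.msd, brute, atol=1e-10)

    def test_unlabeled_particles_rejected(self):
        with pytest.raises(ValidationError, match="leaflet"):
            PlanarTrajectorySet(
                np.arange(5.0), np.zeros((2, 5, 2)), np.array(["upper", "middle"])
            )

    def test_brownian_recovery_within_three_standard_errors(self):
        d_true = 5.0
        traj, _ = gen_brownian_traj(d_true, 1024, 1000, 1.0, seed=2024)
        d_fit, _ = fit_msd_linear(compute_msd(traj), (10.0, 100.0))
        # MSD(t) estimate from N independent particles has relative sampling
        # error ~ sqrt(2 t / (N T_run)) per origin-averaged curve; 3 sigma
        # with a generous bound of 5 % covers the window average.
        assert d_fit == pytest.approx(d_true, rel=0.05)


class TestFitMSDLinear:
    def test_exact_line_returns_d(self):
        lag = np.arange(0.0, 200.0)
        d = 5.0  # um^2/s -> slope 4 * 5e-3 nm^2/ns
        msd = MSDCurve(lag, 4 * d * 1e-3 * lag)
        d_fit, intercept = fit_msd_linear(msd)
        assert d_fit == pytest.approx(d, rel=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_intercept_does_not_bias_d(self):
        lag = np.arange(1.0, 200.0)
        msd = MSDCurve(lag, 4 * 5e-3 * lag + 2.0)
        d_fit, intercept = fit_msd_linear(msd)
        assert d_fit == pytest.approx(5.0, rel=1e-12)
        assert intercept == pytest.approx(2.0, rel=1e-9)

    @pytest.mark.parametrize("window", [(0.0, 50.0), (20.0, 150.0), (5.0, 199.0)])
    def test_any_window_inside_support_recovers_d(self, window):
        lag = np.arange(0.0, 200.0)
        msd = MSDCurve(lag, 4 * 7.5e-3 * lag)
        assert fit_msd_linear(msd, window)[0] == pytest.approx(7.5, rel=1e-12)

    def test_window_outside_support_raises(self):
        msd = MSDCurve(np.arange(0.0, 50.0), np.arange(0.0, 50.0) * 0.01)
        with pytest.raises(ValueError, match="window"):
            fit_msd_linear(msd, (10.0, 100.0))


class TestSaffmanDelbrueckLength:
    def test_reference_value(self):
        assert saffman_delbrueck_length(80.0, 4.0, 0.3228) == pytest.approx(
            495.7, abs=0.1
        )

    def test_equal_viscosities(self):
        assert saffman_delbrueck_length(1.0, 2.0, 1.0) == 1.0

    def test_linear_in_thickness_and_membrane_viscosity(self):
        base = saffman_delbrueck_length(80.0, 4.0, 0.3228)
        assert saffman_delbrueck_length(80.0, 8.0, 0.3228) == pytest.approx(2 * base)
        assert saffman_delbrueck_length(160.0, 4.0, 0.3228) == pytest.approx(2 * base)


class TestDpbcModel:
    def test_monotone_in_box_size(self, geometry):
        L = np.linspace(4.0, 50.0, 200)
        d = dpbc_model(L, 10.0, 80.0, geometry)
        assert np.all(np.diff(d) > 0)

    def test_correction_suppresses_d_in_fitting_regime(self, geometry):
        # boxes far below L_SD measure slower apparent diffusion
        assert dpbc_model(10.0, 10.0, 80.0, geometry) < 10.0

    def test_correction_magnitude_has_thermal_scale(self, geometry):
        # at L = e^xi * L_SD (and no water term) the 2D bracket crosses zero
        from cholbench.diffusion import _pbc_correction_bracket

        l_sd = saffman_delbrueck_length(80.0, geometry.h, geometry.mu_f)
        bracket = _pbc_correction_bracket(
            np.exp(XI_SQUARE_LATTICE) * l_sd, 80.0, geometry
        )
        assert abs(bracket[0]) < 0.05  # small residual from the water term

    def test_nonpositive_parameters_rejected(self, geometry):
        with pytest.raises(ValueError):
            dpbc_model(10.0, -1.0, 80.0, geometry)
        with pytest.raises(ValueError):
            dpbc_model(0.0, 10.0, 80.0, geometry)


class TestFitFiniteSize:
    def test_noiseless_three_point_recovery(self, noiseless_series):
        series, (d_inf, mu_m) = noiseless_series
        fit = fit_finite_size(series)
        assert fit.d_inf == pytest.approx(d_inf, rel=1e-6)
        assert fit.mu_m == pytest.approx(mu_m, rel=1e-6)
        assert fit.l_sd == pytest.approx(
            saffman_delbrueck_length(fit.mu_m, series.geom.h, series.geom.mu_f),
            rel=1e-9,
        )

    @pytest.mark.parametrize("init_mu_m", [50.0, 150.0])
    def test_recovery_independent_of_init(self, noiseless_series, init_mu_m):
        series, (d_inf, mu_m) = noiseless_series
        fit = fit_finite_size(series, init_mu_m=init_mu_m)
        assert fit.d_inf == pytest.approx(d_inf, rel=1e-6)
        assert fit.mu_m == pytest.approx(mu_m, rel=1e-6)

    def test_constant_series_flagged_degenerate(self, geometry):
        series = FiniteSizeSeries(
            [(4.5, 6.0, None), (9.2, 6.0, None), (18.3, 6.0, None)], geometry
        )
        fit = fit_finite_size(series)
        assert fit.degenerate
        assert fit.d_inf == pytest.approx(6.0)

    def test_two_points_interpolated_exactly(self, geometry):
        d = [dpbc_model(L, 8.0, 120.0, geometry) for L in (4.5, 18.3)]
        series = FiniteSizeSeries(
            [(4.5, d[0], None), (18.3, d[1], None)], geometry
        )
        fit = fit_finite_size(series)
        for L, di in zip((4.5, 18.3), d):
            assert dpbc_model(L, fit.d_inf, fit.mu_m, geometry) == pytest.approx(
                di, rel=1e-9
            )


class TestMCErrorPropagation:
    def test_zero_errors_zero_spread(self, geometry):
        series, _ = gen_finite_size_series(
            10.0, 80.0, geometry, [4.5, 9.2, 18.3], rel_noise=0.0
        )
        res = mc_error_propagation(series, n=500, seed=11)
        assert res.d_inf_err == 0.0
        assert np.ptp(res.mu_m_samples) == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_bit_identical(self, geometry):
        series, _ = gen_finite_size_series(
            10.0, 80.0, geometry, [4.5, 9.2, 18.3], rel_noise=0.05, seed=7
        )
        a = mc_error_propagation(series, n=1000, seed=3)
        b = mc_error_propagation(series, n=1000, seed=3)
        assert a.d_inf_err == b.d_inf_err
        np.testing.assert_array_equal(a.mu_m_samples, b.mu_m_samples)

    def test_unbiased_at_small_noise(self, geometry):
        series, _ = gen_finite_size_series(
            10.0, 80.0, geometry, [4.5, 9.2, 18.3], rel_noise=0.0
        )
        pts = [(L, d, 0.05 * d) for L, d, _ in series.points]
        noisy = FiniteSizeSeries(pts, geometry)
        res = mc_error_propagation(noisy, n=10000, seed=19)
        assert res.d_inf == pytest.approx(10.0, rel=1e-9)  # base fit exact
        # the nonlinear fit leaves a second-order bias in the sample mean;
        # it must stay far below the propagated spread itself
        assert abs(np.mean(res.d_inf_samples) - 10.0) < 0.05 * res.d_inf_err

    def test_spread_monotone_in_error_scale(self, geometry):
        spreads = []
        for rel in (0.01, 0.03, 0.05):
            series, _ = gen_finite_size_series(
                10.0, 80.0, geometry, [4.5, 9.2, 18.3], rel_noise=0.0
            )
            pts = [(L, d, rel * d) for L, d, _ in series.points]
            res = mc_error_propagation(
                FiniteSizeSeries(pts, geometry), n=2000, seed=23
            )
            spreads.append(res.d_inf_err)
        assert spreads[0] < spreads[1] < spreads[2]

    def test_missing_errors_rejected(self, geometry):
        series = FiniteSizeSeries(
            [(4.5, 4.0, None), (9.2, 4.7, None), (18.3, 5.3, None)], geometry
        )
        with pytest.raises(ValidationError, match="d_err"):
            mc_error_propagation(series, n=10, seed=0)
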