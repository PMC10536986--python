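"""Density smoothing, thickness, form factors, APL and partial areas."""

import numpy as np
import pytest

from cholbench import (
    DensityProfile,
    area_per_lipid,
    bilayer_thickness,
    chol_partial_area,
    form_factor,
    form_factor_minima,
    smooth_density,
)
from cholbench.observables import ValidationError
from cholbench.synthetic import SDPDensitySpec, default_z_grid, gen_sdp_density, gen_slab_density


def _flat(value=333.0, n=101):
    z = np.linspace(-2.5, 2.5, n)
    return DensityProfile(z, np.full(n, value), 333.0)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        prof = _flat()
        np.testing.assert_array_equal(smooth_density(prof).rho, prof.rho)

    def test_unit_impulse_spreads_to_five_points(self):
        z = np.linspace(-1, 1, 21)
        rho = np.zeros(21)
        rho[10] = 1.0
        out = smooth_density(DensityProfile(z, rho, 0.0))
        np.testing.assert_allclose(out.rho[8:13], 0.2)
        assert np.all(out.rho[:8] == 0) and np.all(out.rho[13:] == 0)

    def test_window_one_is_identity(self):
        prof = gen_sdp_density()[0]
        np.testing.assert_array_equal(smooth_density(prof, 1).rho, prof.rho)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_density(_flat(), 4)

    def test_edges_use_shrinking_symmetric_window(self):
        z = np.linspace(0, 1, 6) - 0.5
        rho = np.arange(6.0) ** 2
        out = smooth_density(DensityProfile(z, rho, 0.0))
        assert out.rho[0] == rho[0]  # 1-point window at the edge
        assert out.rho[1] == pytest.approx(rho[:3].mean())  # 3-point window


class TestThickness:
    def test_two_gaussian_profile(self):
        z = default_z_grid(4.0, 0.01)
        rho = 333.0 + 100 * (
            np.exp(-0.5 * ((z - 2.0) / 0.3) ** 2)
            + np.exp(-0.5 * ((z + 2.0) / 0.3) ** 2)
        )
        assert bilayer_thickness(DensityProfile(z, rho, 333.0)) == pytest.approx(
            4.0, abs=0.01
        )

    def test_sdp_fixture_recovers_ground_truth(self, sdp_profile):
        profile, spec = sdp_profile
        assert bilayer_thickness(profile) == pytest.approx(
            spec.thickness, abs=profile.dz
        )

    def test_flat_profile_raises(self):
        with pytest.raises(ValidationError, match="headgroup peak"):
            bilayer_thickness(_flat())

    def test_mirror_invariance(self, sdp_profile):
        profile, _ = sdp_profile
        mirrored = DensityProfile(profile.z, profile.rho[::-1], profile.solvent_rho)
        assert bilayer_thickness(mirrored) == pytest.approx(
            bilayer_thickness(profile), abs=1e-12
        )

    def test_headgroupless_spec_raises(self):
        spec = SDPDensitySpec(hg_amplitude=0.0, methyl_depth=30.0)
        profile, _ = gen_sdp_density(spec)
        with pytest.raises(ValidationError, match="headgroup peak"):
            bilayer_thickness(profile)


class TestFormFactor:
    def test_zero_contrast_gives_zero(self):
        ff = form_factor(_flat(), np.arange(0.01, 5.0, 0.01))
        np.testing.assert_allclose(ff.f_abs, 0.0, atol=1e-12)

    def test_f_at_zero_q_equals_integrated_contrast(self, sdp_profile):
        profile, _ = sdp_profile
        ff = form_factor(profile, np.array([0.0, 0.1]))
        expected = abs(np.trapezoid(profile.rho - profile.solvent_rho, profile.z))
        assert ff.f_abs[0] == pytest.approx(expected, rel=1e-12)

    def test_slab_matches_closed_form_below_fifth_zero(self):
        d, contrast = 2.0, -60.0
        slab = gen_slab_density(d, contrast, default_z_grid(4.0, 0.001))
        q = np.arange(0.01, 10.0, 0.005)
        ff = form_factor(slab, q)
        exact = np.abs(2 * contrast * np.sin(q * d) / q)
        sel = (q < 5 * np.pi / d) & (exact > 0.01 * 2 * abs(contrast) * d)
        rel = np.abs(ff.f_abs - exact)[sel] / exact[sel]
        assert rel.max() < 0.005

    def test_gaussian_contrast_transforms_to_gaussian(self):
        z = default_z_grid(5.0, 0.005)
        sigma = 0.5
        rho = 333.0 + 80 * np.exp(-0.5 * (z / sigma) ** 2)
        q = np.arange(0.01, 6.0, 0.005)
        ff = form_factor(DensityProfile(z, rho, 333.0), q)
        exact = 80 * sigma * np.sqrt(2 * np.pi) * np.exp(-0.5 * (q * sigma) ** 2)
        np.testing.assert_allclose(ff.f_abs, exact, rtol=5e-4)
        with pytest.raises(ValidationError, match="insufficient minima"):
            form_factor_minima(ff, 1)

    def test_asymmetric_grid_rejected(self):
        z = np.linspace(-1.0, 2.0, 31)
        with pytest.raises(ValidationError, match="symmetric"):
            form_factor(DensityProfile(z, np.full(31, 300.0), 333.0))


class TestFormFactorMinima:
    @pytest.mark.parametrize("d", [2.0, 4.0])
    def test_slab_minima_at_sine_zeros(self, d):
        slab = gen_slab_density(d, -60.0, default_z_grid(2.5 * d, 0.001))
        q = np.arange(0.01, 10.0, 0.005)
        minima = form_factor_minima(form_factor(slab, q), 2)
        assert minima[0] == pytest.approx(np.pi / d, abs=0.005)
        assert minima[1] == pytest.approx(2 * np.pi / d, abs=0.005)

    def test_doubling_thickness_halves_minima(self):
        q = np.arange(0.01, 10.0, 0.005)
        m2 = form_factor_minima(
            form_factor(gen_slab_density(2.0, -60.0, default_z_grid(5.0, 0.001)), q), 2
        )
        m4 = form_factor_minima(
            form_factor(gen_slab_density(4.0, -60.0, default_z_grid(10.0, 0.001)), q), 2
        )
        np.testing.assert_allclose(np.array(m4), np.array(m2) / 2, rtol=2e-3)

    def test_parabolic_refinement_beats_grid_argmin(self):
        d = 2.0
        slab = gen_slab_density(d, -60.0, default_z_grid(5.0, 0.001))
        q = np.arange(0.01, 4.0, 0.005)
        ff = form_factor(slab, q)
        refined = form_factor_minima(ff, 1)[0]
        grid_min = q[np.argmin(np.where((q > 1.0) & (q < 2.0), ff.f_abs, np.inf))]
        assert abs(refined - np.pi / d) <= abs(grid_min - np.pi / d)


class TestAreaPerLipid:
    def test_table_box_constant_area(self):
        # 4.4 nm box edge, 32 POPC per leaflet
        point = area_per_lipid(np.full(100, 4.4**2), n_pl_leaflet=32)
        assert point.apl == pytest.approx(0.605, abs=1e-6)
        assert point.se == 0.0

    def test_alternating_series_mean(self):
        point = area_per_lipid(np.array([19.0, 21.0] * 10), n_pl_leaflet=1)
        assert point.apl == pytest.approx(20.0)

    def test_block_error_matches_hand_computation(self):
        series = np.repeat([10.0, 12.0, 11.0, 9.0, 13.0], 4)
        point = area_per_lipid(series, n_pl_leaflet=2, n_blocks=5)
        means = np.array([10.0, 12.0, 11.0, 9.0, 13.0])
        assert point.se == pytest.approx(means.std() / np.sqrt(5) / 2)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValidationError, match="n_blocks"):
            area_per_lipid(np.ones(3), n_pl_leaflet=1, n_blocks=5)


class TestCholPartialArea:
    def test_constant_apl_gives_zero(self):
        # APL fixed: total leaflet area grows with N_chol? No - A_tot = n_pc*apl
        # does not change, so the partial area vanishes.
        curve = chol_partial_area([(0.0, 0.65), (20.0, 0.65), (40.0, 0.65)], 64)
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-12)

    def test_linear_growth_recovers_slope(self):
        # build APL so that A_tot = A0 + a * N_chol exactly
        n_pc, a, a0 = 64, 0.3, 40.0
        pts = []
        for pct in (0.0, 10.0, 20.0, 30.0):
            x = pct / 100.0
            n_chol = n_pc * x / (1 - x)
            pts.append((pct, (a0 + a * n_chol) / n_pc))
        curve = chol_partial_area(pts, n_pc)
        np.testing.assert_allclose(curve.values, a, rtol=1e-9)

    def test_condensing_effect_is_negative(self):
        # APL dropping fast enough that the total leaflet area shrinks
        pts = [(0.0, 0.68), (10.0, 0.60), (20.0, 0.52), (30.0, 0.46)]
        curve = chol_partial_area(pts, 64)
        assert np.all(curve.values < 0)

    def test_full_cholesterol_fraction_singular(self):
        with pytest.raises(ValidationError, match="singular"):
            chol_partial_area([(0.0, 0.65), (100.0, 0.4)], 64)
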