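"""Slab optics, design calculators and Debye PSF metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import j0 as bessel_j0

from mfias import optics
from mfias.optics import (
    GlassSlab,
    OpticalConfig,
    best_focus_index,
    compute_psf,
    debye_radial_intensity,
    enclosed_energy,
    focal_shift,
    fwhm,
    glass_interval,
    num_layers,
    slab_spherical_aberration,
    strehl_ratio,
)


class TestSlabFormulas:
    def test_focal_shift_printed_value(self):
        # 2.4 mm of n=1.5 glass moves the focus 0.8 mm deeper
        assert focal_shift(GlassSlab(2.4, 1.5)) == pytest.approx(800.0)

    def test_focal_shift_open_slot_is_zero(self):
        assert focal_shift(GlassSlab(0.0, 1.5)) == 0.0

    def test_focal_shift_derived_value(self):
        assert focal_shift(GlassSlab(1.8, 1.52)) == pytest.approx(615.789, abs=1e-2)

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            GlassSlab(-0.1, 1.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        d=st.floats(0.01, 5.0),
        n=st.floats(1.2, 2.0),
    )
    def test_focal_shift_linear_in_thickness(self, d, n):
        assert focal_shift(GlassSlab(2 * d, n)) == pytest.approx(
            2 * focal_shift(GlassSlab(d, n)), rel=1e-12
        )

    def test_aberration_coefficient_n15(self):
        # (n^2-1)/(8n^3) at n=1.5 is ~1/20, the rounded rule of thumb
        cfg = OpticalConfig()
        w = slab_spherical_aberration(GlassSlab(1.0, 1.5), cfg)
        theta0 = cfg.half_angle_rad
        assert w == pytest.approx(1.25 / 27 * 1000.0 * theta0**4, rel=1e-12)
        assert w == pytest.approx(1000.0 * theta0**4 / 20.0, rel=0.08)

    def test_aberration_vanishes_without_glass_or_contrast(self):
        cfg = OpticalConfig()
        assert slab_spherical_aberration(GlassSlab(0.0, 1.5), cfg) == 0.0
        # index-matched slab aberrates (almost) nothing
        w = slab_spherical_aberration(GlassSlab(1.0, 1.0 + 1e-9), cfg)
        assert w == pytest.approx(0.0, abs=1e-6)

    def test_aberration_monotone_in_thickness_and_angle(self):
        lo = OpticalConfig(numerical_aperture=0.1)
        hi = OpticalConfig(numerical_aperture=0.3)
        assert slab_spherical_aberration(GlassSlab(1.0, 1.5), hi) > slab_spherical_aberration(
            GlassSlab(1.0, 1.5), lo
        )
        assert slab_spherical_aberration(GlassSlab(2.0, 1.5), hi) > slab_spherical_aberration(
            GlassSlab(1.0, 1.5), hi
        )


class TestDesignCalculators:
    def test_glass_interval_printed_value(self):
        assert glass_interval(25.0, 1.5) == pytest.approx(150.0)

    def test_glass_interval_derived(self):
        assert glass_interval(25.0, 1.52) == pytest.approx(146.1538, abs=1e-3)

    def test_glass_interval_high_index_limit(self):
        assert glass_interval(25.0, 1e9) == pytest.approx(50.0, rel=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(length=st.floats(1.0, 200.0), n=st.floats(1.1, 2.5))
    def test_interval_shift_consistency(self, length, n):
        # the designed thickness step produces a focal step of exactly 2L
        step_mm = glass_interval(length, n) / 1000.0
        assert focal_shift(GlassSlab(step_mm, n)) == pytest.approx(2 * length, rel=1e-9)

    def test_num_layers_printed_value(self):
        assert num_layers(450.0, 25.0) == 10

    def test_num_layers_edge_cases(self):
        assert num_layers(0.0, 25.0) == 1
        assert num_layers(50.0, 25.0) == 2

    def test_num_layers_warns_on_non_integral(self):
        with pytest.warns(UserWarning):
            assert num_layers(460.0, 25.0) == 10

    def test_relay_scaling(self):
        assert optics.relay_shift_scaling(1.0) == 1.0
        # 1 mm of image-space shift maps to 10 um at the sample for M=10
        assert 1000.0 * optics.relay_shift_scaling(10.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            optics.relay_shift_scaling(0.0)

    def test_multi_disc_positions(self):
        count, pos = optics.multi_disc_positions(3, 10, 4)
        assert count == 120 and len(pos) == 120
        assert len(np.unique(pos)) == 120
        # nested increments tile a uniform ladder
        assert np.allclose(np.diff(pos), pos[1] - pos[0])
        assert optics.multi_disc_positions(1, 1, 1)[0] == 1

    def test_photon_budget(self):
        b = optics.photon_budget(10)
        assert b == {"illumination_power_factor": 10.0, "dose_vs_full_3d_scan": 0.1}
        assert optics.photon_budget(1)["dose_vs_full_3d_scan"] == 1.0

    @settings(derandomize=True, max_examples=20)
    @given(n=st.integers(1, 100))
    def test_dose_power_identity(self, n):
        b = optics.photon_budget(n)
        assert b["illumination_power_factor"] * b["dose_vs_full_3d_scan"] == pytest.approx(1.0)

    def test_design_system_summary(self):
        spec = optics.design_system(450.0, 25.0, 1.5, aperture_mm=40.0)
        assert spec.num_layers == 10
        assert spec.glass_interval_um == pytest.approx(150.0)
        # the packing rule is approximate; the printed figure is ~100 mm
        assert 70.0 < spec.min_disc_radius_mm < 130.0


class TestDebyePSF:
    def test_airy_fwhm(self, cfg):
        psf = compute_psf(cfg, None)
        plane = psf.intensity[best_focus_index(psf)]
        mid = plane.shape[0] // 2
        measured = fwhm(plane[mid], psf.lateral_spacing_um)
        assert measured == pytest.approx(0.51 * cfg.wavelength_um / cfg.numerical_aperture, rel=0.05)

    def test_lateral_symmetry(self, cfg):
        psf = compute_psf(cfg, GlassSlab(1.2, 1.5))
        plane = psf.intensity[best_focus_index(psf)]
        assert np.allclose(plane, plane[::-1, :], rtol=1e-10)
        assert np.allclose(plane, plane[:, ::-1], rtol=1e-10)

    def test_axial_extent_scales_with_na_squared(self):
        # half-intensity axial range ratio between NA 0.3 and NA 0.1 is ~(3)^2
        z = np.linspace(0, 150, 601)

        def half_range(na):
            c = OpticalConfig(numerical_aperture=na)
            prof = debye_radial_intensity(c, None, np.zeros(1), z)[:, 0]
            prof /= prof[0]
            return z[np.argmax(prof < 0.5)]

        ratio = half_range(0.1) / half_range(0.3)
        assert ratio == pytest.approx(9.0, rel=0.15)

    def test_pupil_sampling_converged(self, cfg):
        coarse = debye_radial_intensity(cfg, GlassSlab(2.4, 1.5), np.zeros(1), np.array([800.0]), 256)
        fine = debye_radial_intensity(cfg, GlassSlab(2.4, 1.5), np.zeros(1), np.array([800.0]), 512)
        assert abs(coarse[0, 0] - fine[0, 0]) / fine[0, 0] < 0.01

    def test_quadrature_matches_2d_pupil_oracle(self, cfg):
        # brute force: direct 2D midpoint quadrature over the circular pupil
        theta0 = cfg.half_angle_rad
        k = 2 * np.pi / cfg.wavelength_um
        n = 201
        tx = np.linspace(-theta0, theta0, n)
        gx, gy = np.meshgrid(tx, tx)
        tt = np.hypot(gx, gy)
        inside = tt <= theta0
        w040 = slab_spherical_aberration(GlassSlab(1.0, 1.5), cfg)

        r_test = np.array([0.0, 0.5, 1.0, 2.0])
        z_rel = 5.0  # defocus relative to the slab-shifted focus
        tts = np.where(tt > 0, tt, 1.0)
        # direction cosine of each pupil ray along x (the field point offset axis)
        sx = np.sin(tt) * gx / tts
        weight = np.where(tt > 0, np.sin(tt) / tts, 1.0)
        oracle = []
        for r in r_test:
            phase = np.exp(
                1j * k * (
                    r * sx
                    + z_rel * np.cos(tt)
                    + w040 * (np.sin(tt) / np.sin(theta0)) ** 4
                )
            )
            integ = np.where(inside, np.sqrt(np.cos(tt)) * phase, 0)
            oracle.append(abs((integ * weight).sum() * (tx[1] - tx[0]) ** 2 / (2 * np.pi)) ** 2)
        oracle = np.array(oracle)
        slab = GlassSlab(1.0, 1.5)
        z_abs = focal_shift(slab, cfg) + z_rel
        prod = debye_radial_intensity(cfg, slab, r_test, np.array([z_abs]))[0]
        assert np.allclose(prod / prod[0], oracle / oracle[0], atol=0.01)

    def test_plane_energy_conserved_across_defocus(self, cfg):
        psf = compute_psf(cfg, None, z_planes_um=np.array([-20.0, -10.0, 0.0, 10.0, 20.0]),
                          lateral_extent_um=60.0)
        energies = psf.intensity.sum(axis=(1, 2))
        assert energies.max() / energies.min() - 1 < 0.02


class TestPSFMetrics:
    def test_strehl_identity(self, cfg):
        psf = compute_psf(cfg, None)
        assert strehl_ratio(psf, psf) == pytest.approx(1.0)

    def test_strehl_below_080_at_18mm(self, cfg):
        ref = compute_psf(cfg, None)
        ab = compute_psf(cfg, GlassSlab(1.8, 1.5))
        assert strehl_ratio(ab, ref) < 0.8

    def test_strehl_and_enclosed_energy_monotone_in_thickness(self, cfg):
        ref = compute_psf(cfg, None)
        strehls, ees = [], []
        for d in (0.0, 0.8, 1.6, 2.4):
            slab = GlassSlab(d, 1.5) if d else None
            psf = compute_psf(cfg, slab)
            strehls.append(strehl_ratio(psf, ref))
            ees.append(enclosed_energy(psf, 5.0))
        assert all(a >= b - 1e-9 for a, b in zip(strehls, strehls[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(ees, ees[1:]))

    def test_strehl_spacing_mismatch_rejected(self, cfg):
        a = compute_psf(cfg, None)
        b = compute_psf(cfg, None, lateral_spacing_um=0.1)
        with pytest.raises(ValueError):
            strehl_ratio(a, b)

    def test_enclosed_energy_full_grid_is_one(self, cfg):
        psf = compute_psf(cfg, None)
        # largest circle that fits
        half = (psf.intensity.shape[1] - 1) // 2 * psf.lateral_spacing_um
        assert enclosed_energy(psf, half - psf.lateral_spacing_um) > 0.97

    def test_enclosed_energy_at_airy_rings(self, cfg):
        # 83.8% of an Airy pattern's energy lies inside the first dark ring
        # (radius 0.61 lambda/NA); the 1.22 lambda/NA circle holds ~91%
        psf = compute_psf(cfg, None)
        first_ring = 0.61 * cfg.wavelength_um / cfg.numerical_aperture
        assert enclosed_energy(psf, first_ring) == pytest.approx(0.838, abs=0.02)
        assert enclosed_energy(psf, 2 * first_ring) == pytest.approx(0.91, abs=0.02)

    def test_enclosed_energy_monotone_in_radius(self, cfg):
        psf = compute_psf(cfg, GlassSlab(2.4, 1.5))
        vals = [enclosed_energy(psf, r) for r in (1.0, 2.0, 5.0, 10.0)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_enclosed_energy_radius_beyond_grid_rejected(self, cfg):
        psf = compute_psf(cfg, None)
        with pytest.raises(ValueError):
            enclosed_energy(psf, 1000.0)

    def test_worst_case_enclosed_energy(self, cfg):
        psf = compute_psf(cfg, GlassSlab(2.4, 1.5))
        assert enclosed_energy(psf, 5.0) >= 0.90


class TestFWHM:
    def test_gaussian_closed_form(self):
        x = np.linspace(-10, 10, 2001)
        sigma = 1.7
        profile = np.exp(-(x**2) / (2 * sigma**2))
        assert fwhm(profile, x[1] - x[0]) == pytest.approx(2.3548 * sigma, rel=1e-3)

    def test_top_hat_width(self):
        profile = np.zeros(101)
        profile[40:61] = 1.0
        assert fwhm(profile, 0.5) == pytest.approx(21 * 0.5, abs=0.5)

    def test_peak_on_boundary_flagged(self):
        with pytest.raises(ValueError):
            fwhm(np.array([5.0, 3.0, 1.0, 0.5]), 1.0)
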