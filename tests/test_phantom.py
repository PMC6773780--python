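"""Phantom generator: shape profile, ground truth, morphs, fluctuation stacks."""

import dataclasses

import numpy as np
import pytest

from holocyte import phantom
from holocyte.phantom import (PhantomParams, SceneConfig, biconcave_thickness,
                              c0_for_sphericity, ground_truth_record,
                              morph_for_temperature, sphericity_of_profile,
                              thickness_to_opd)


class TestThicknessProfile:
    def test_rim_is_zero(self):
        p = PhantomParams()
        assert biconcave_thickness(1.0, p) == 0.0
        assert biconcave_thickness(1.7, p) == 0.0

    def test_center_is_c0(self):
        p = PhantomParams(shape_c0=0.81)
        assert biconcave_thickness(0.0, p) == pytest.approx(0.81)

    def test_half_radius_value_matches_direct_arithmetic(self):
        # independent evaluation: sqrt(1-rho^2) * (c0 + c2 rho^2 + c4 rho^4)
        p = PhantomParams(shape_c0=0.81, shape_c2=7.83, shape_c4=-4.39)
        expected = np.sqrt(1.0 - 0.25) * (0.81 + 7.83 * 0.25 + (-4.39) * 0.0625)
        assert biconcave_thickness(0.5, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_rho_rejected(self):
        with pytest.raises(ValueError):
            biconcave_thickness(-0.1, PhantomParams())

    def test_profile_nonnegative_everywhere(self):
        p = PhantomParams()
        rho = np.linspace(0, 1.5, 400)
        assert np.all(biconcave_thickness(rho, p) >= 0)


class TestOpdConversion:
    def test_scalar_value(self):
        assert thickness_to_opd(2.0, 1.40, 1.34) == pytest.approx(120.0)

    def test_zero_thickness(self):
        assert thickness_to_opd(0.0, 1.40, 1.34) == 0.0

    def test_uniform_disc_maps_pointwise(self):
        t = np.zeros((8, 8))
        t[2:6, 2:6] = 1.5
        opd = thickness_to_opd(t, 1.40, 1.34)
        assert np.all(opd[2:6, 2:6] == pytest.approx(90.0))
        assert np.all(opd[t == 0] == 0.0)

    def test_index_ordering_enforced(self):
        with pytest.raises(ValueError):
            thickness_to_opd(1.0, 1.34, 1.40)


class TestGroundTruth:
    def test_psa_closed_form(self):
        gt = ground_truth_record(PhantomParams(cell_radius_um=4.37))
        assert gt.psa_um2 == pytest.approx(np.pi * 4.37**2, rel=1e-12)
        assert gt.psa_um2 == pytest.approx(60.0, rel=0.01)

    def test_constant_polynomial_sphericity_is_envelope_ratio(self):
        # with c2 = c4 = 0 the profile is the spherical-cap envelope alone,
        # so k = 1/sqrt(1 - 0.25) exactly (the dimple-free limit; > 1)
        p = PhantomParams(shape_c0=1.0, shape_c2=0.0, shape_c4=0.0)
        k = sphericity_of_profile(p)
        assert k == pytest.approx(1.0 / np.sqrt(0.75), rel=1e-12)

    def test_mch_quadrature_vs_dense_pixel_summation(self):
        # brute-force 2-D oracle at 0.01 um pitch
        p = PhantomParams(cell_radius_um=4.37)
        gt = ground_truth_record(p)
        pitch = 0.01
        n = int(np.ceil(2 * p.cell_radius_um / pitch)) + 3
        c = n / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        rho = np.hypot(yy - c, xx - c) * pitch / p.cell_radius_um
        t = biconcave_thickness(np.clip(rho, 0, None), p)
        t[rho >= 1] = 0.0
        opd = thickness_to_opd(t, p.n_cell, p.n_medium)
        inside = rho < 1
        mean_opd = opd[inside].mean()
        psa = inside.sum() * pitch**2
        mch_2d = mean_opd * psa * 1e-3 / (p.refraction_increment_alpha * 100)
        assert mch_2d == pytest.approx(gt.mch_pg, rel=1e-3)

    def test_scenario_bases_match_reported_magnitudes(self):
        sealed = ground_truth_record(
            phantom.scenario_base_params(phantom.sealed_scenario())
        )
        assert sealed.psa_um2 == pytest.approx(60.0, rel=1e-6)
        assert sealed.sphericity_k == pytest.approx(0.65, rel=1e-6)
        assert sealed.mch_pg == pytest.approx(32.3, rel=1e-6)
        chamber = ground_truth_record(
            phantom.scenario_base_params(phantom.chamber_scenario())
        )
        assert chamber.psa_um2 == pytest.approx(49.0, rel=1e-6)
        assert chamber.mch_pg == pytest.approx(30.5, rel=1e-6)


class TestMorph:
    def test_identity_scenario_leaves_params_unchanged(self, sealed_base):
        scen = dataclasses.replace(
            phantom.sealed_scenario(), psa_slope_um2_per_c=0.0,
            sphericity_slope_per_c=0.0,
        )
        m = morph_for_temperature(sealed_base, scen, 37.0)
        assert m.cell_radius_um == pytest.approx(sealed_base.cell_radius_um, rel=1e-12)
        assert m.shape_c0 == pytest.approx(sealed_base.shape_c0, rel=1e-9)

    def test_sealed_psa_increases(self, sealed_base):
        scen = phantom.sealed_scenario()
        lo = ground_truth_record(morph_for_temperature(sealed_base, scen, 17.0))
        hi = ground_truth_record(morph_for_temperature(sealed_base, scen, 41.0))
        assert hi.psa_um2 > lo.psa_um2
        assert hi.psa_um2 == pytest.approx(64.0, rel=1e-6)

    def test_sealed_sphericity_monotone_decreasing(self, sealed_base):
        scen = phantom.sealed_scenario()
        temps = np.linspace(17.0, 41.0, 13)
        ks = [
            sphericity_of_profile(morph_for_temperature(sealed_base, scen, t))
            for t in temps
        ]
        assert np.all(np.diff(ks) < 0)

    def test_morph_conserves_dry_mass(self, sealed_base):
        scen = phantom.sealed_scenario()
        m0 = phantom.dry_mass_pg(sealed_base)
        for t in scen.temperatures_c:
            m = phantom.dry_mass_pg(morph_for_temperature(sealed_base, scen, t))
            assert m == pytest.approx(m0, rel=1e-9)

    def test_out_of_range_temperature_rejected(self, sealed_base):
        with pytest.raises(ValueError):
            morph_for_temperature(sealed_base, phantom.sealed_scenario(), 50.0)

    def test_c0_solver_inverts_profile_sphericity(self):
        p = PhantomParams()
        k = sphericity_of_profile(p)
        assert c0_for_sphericity(k, p.shape_c2, p.shape_c4) == pytest.approx(
            p.shape_c0, rel=1e-12
        )


class TestSceneRendering:
    def test_opd_zero_outside_positive_inside(self, small_scene, sealed_base):
        scene, cfg = small_scene
        mask = phantom.analytic_cell_mask(sealed_base, cfg)
        shrunk = phantom.analytic_cell_mask(
            dataclasses.replace(
                sealed_base, cell_radius_um=0.97 * sealed_base.cell_radius_um
            ),
            cfg,
        )
        assert np.all(scene[~mask] == 0.0)
        assert np.all(scene[shrunk] > 0.0)

    def test_pixel_psa_within_perimeter_band(self, sealed_base):
        cfg = SceneConfig(grid_size=512, pixel_pitch_um=0.18, n_cells=1)
        scene = phantom.render_scene([sealed_base], cfg)
        pixel_psa = np.count_nonzero(scene > 0) * cfg.pixel_pitch_um**2
        analytic = np.pi * sealed_base.cell_radius_um**2
        band = 2 * np.pi * sealed_base.cell_radius_um * cfg.pixel_pitch_um
        assert abs(pixel_psa - analytic) <= band

    def test_same_seed_same_scene(self, sealed_base):
        cfg = SceneConfig(grid_size=128, pixel_pitch_um=0.4, n_cells=3, seed=5)
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        c1 = phantom.sample_cohort(3, sealed_base, rng1)
        c2 = phantom.sample_cohort(3, sealed_base, rng2)
        assert all(a == b for a, b in zip(c1, c2))


class TestFluctuationStack:
    def _cell_setup(self):
        p = PhantomParams(cell_radius_um=4.0)
        cfg = SceneConfig(grid_size=64, pixel_pitch_um=0.36, n_cells=1)
        base = phantom.render_scene([p], cfg)
        mask = base > 20.0
        rows, cols = np.nonzero(mask)
        centroid = (rows.mean(), cols.mean())
        radius = np.sqrt(mask.sum() / np.pi)
        return base, mask, centroid, radius

    def test_zero_amplitude_gives_identical_frames(self):
        base, mask, centroid, radius = self._cell_setup()
        amp = np.zeros_like(base)
        stack = phantom.generate_fluctuation_stack(base, amp, 5, 0)
        assert np.array_equal(stack[0], base)
        assert np.array_equal(stack[4], base)

    def test_same_seed_bit_identical(self):
        base, mask, centroid, radius = self._cell_setup()
        amp = phantom.fluctuation_amplitude_map(mask, centroid, radius, 4.0, 2.0)
        s1 = phantom.generate_fluctuation_stack(base, amp, 20, 7, bkgd_noise_nm=1.0)
        s2 = phantom.generate_fluctuation_stack(base, amp, 20, 7, bkgd_noise_nm=1.0)
        assert np.array_equal(s1, s2)

    def test_per_pixel_std_converges_to_amplitude_map(self):
        # law of large numbers at T=10,000 (relative SE ~ 1/sqrt(2T))
        base, mask, centroid, radius = self._cell_setup()
        amp = phantom.fluctuation_amplitude_map(mask, centroid, radius, 5.0, 3.0)
        stack = phantom.generate_fluctuation_stack(
            base, amp, 10_000, 11, dtype=np.float32
        )
        sd = np.std(stack, axis=0, ddof=1, dtype=np.float64)
        rel = sd[mask] / amp[mask] - 1.0
        assert abs(rel.mean()) < 0.01
        assert np.quantile(np.abs(rel), 0.95) < 0.025
        assert np.abs(rel).max() < 0.04

    def test_mean_converges_to_base(self):
        base, mask, centroid, radius = self._cell_setup()
        amp = phantom.fluctuation_amplitude_map(mask, centroid, radius, 4.0, 4.0)
        stack = phantom.generate_fluctuation_stack(
            base, amp, 10_000, 3, dtype=np.float32
        )
        dev = np.abs(stack.mean(axis=0, dtype=np.float64) - base)
        assert dev[mask].max() < 3.5 * 4.0 / np.sqrt(10_000)

    def test_dimple_ring_regions_receive_their_amplitudes(self):
        base, mask, centroid, radius = self._cell_setup()
        amp = phantom.fluctuation_amplitude_map(mask, centroid, radius, 4.0, 2.0)
        yy = np.arange(mask.shape[0])[:, None] - centroid[0]
        xx = np.arange(mask.shape[1])[None, :] - centroid[1]
        r = np.hypot(yy, xx)
        assert np.all(amp[mask & (r < 0.4 * radius)] == 2.0)
        assert np.all(amp[mask & (r > 0.6 * radius)] == 4.0)
        assert np.all(amp[~mask] == 0.0)

    def test_ar1_preserves_stationary_std(self):
        base, mask, centroid, radius = self._cell_setup()
        amp = phantom.fluctuation_amplitude_map(mask, centroid, radius, 4.0, 4.0)
        stack = phantom.generate_fluctuation_stack(
            base, amp, 4000, 13, ar1_rho=0.6, dtype=np.float32
        )
        sd = np.std(stack, axis=0, ddof=1, dtype=np.float64)
        # AR(1) inflates the variance of the std estimate, not its target
        assert sd[mask].mean() == pytest.approx(4.0, rel=0.05)
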