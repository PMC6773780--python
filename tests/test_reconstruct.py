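"""Reconstruction chain: sideband isolation, demodulation, Fresnel, phase, OPD."""

import dataclasses

import numpy as np
import pytest

from holocyte import phantom
from holocyte.forward import (ComplexField, OpticalConfig, object_wave,
                              propagate, record_hologram, reference_wave)
from holocyte.reconstruct import (NoSidebandError, PhaseMap,
                                  ReconstructionConfig, SpatialFilter,
                                  compensate_background, demodulate,
                                  extract_phase, filter_real_image,
                                  fresnel_reconstruct, locate_sideband,
                                  phase_to_opd, reconstruct_hologram,
                                  unwrap_phase)


class TestLocateSideband:
    def test_center_matches_tilt_bins(self, midsize_hologram):
        holo, scene, optics = midsize_hologram
        filt = locate_sideband(holo)
        n = holo.data.shape[0]
        assert filt.center == (n // 4, n // 4)
        assert filt.radius == pytest.approx(np.hypot(n / 4, n / 4) / 2)

    def test_zero_tilt_raises(self):
        cfg = OpticalConfig(pixel_pitch_um=0.18, tilt_kx=0.0, tilt_ky=0.0)
        obj = object_wave(np.zeros((128, 128)), cfg)
        ref = reference_wave(cfg, (128, 128))
        holo = record_hologram(obj, ref, cfg)
        with pytest.raises(NoSidebandError):
            locate_sideband(holo)

    def test_filter_excludes_dc(self, midsize_hologram):
        holo, scene, optics = midsize_hologram
        filt = locate_sideband(holo)
        assert filt.mask(holo.data.shape)[0, 0] == 0.0


class TestFilterRealImage:
    def test_all_pass_returns_hologram_exactly(self, midsize_hologram):
        holo, scene, optics = midsize_hologram
        out = filter_real_image(holo, SpatialFilter.all_pass())
        assert np.allclose(out.data.real, holo.data, atol=1e-9)
        assert np.allclose(out.data.imag, 0.0, atol=1e-9)

    def test_masking_is_idempotent(self, midsize_hologram):
        holo, scene, optics = midsize_hologram
        filt = locate_sideband(holo)
        once = filter_real_image(holo, filt)
        twice_spec = np.fft.fft2(once.data) * filt.mask(holo.data.shape)
        twice = np.fft.ifft2(twice_spec)
        assert np.allclose(twice, once.data, atol=1e-12)

    def test_unit_modulus_in_cell_free_region(self, midsize_hologram):
        # noise-free, |R| = 1: filtered field modulus ~ |O| = 1 off the cell
        holo, scene, optics = midsize_hologram
        filt = locate_sideband(holo)
        out = filter_real_image(holo, filt)
        far = scene == 0
        # erode the evaluation region away from the cell's ringing halo
        from scipy.ndimage import binary_erosion

        far = binary_erosion(far, iterations=30)
        dev = np.abs(out.data[far]) - 1.0
        assert np.sqrt(np.mean(dev**2)) < 1e-3


class TestDemodulate:
    def test_matched_tilt_gives_constant_phase(self):
        cfg = OpticalConfig(pixel_pitch_um=0.18)
        obj = object_wave(np.zeros((256, 256)), cfg)
        ref = reference_wave(cfg, (256, 256))
        holo = record_hologram(obj, ref, cfg)
        filt = locate_sideband(holo)
        field = filter_real_image(holo, filt)
        kx, ky = cfg.resolved_tilt()
        rcfg = ReconstructionConfig(pixel_pitch_um=0.18, tilt_kx=kx, tilt_ky=ky)
        out = demodulate(field, rcfg)
        interior = np.angle(out.data[32:-32, 32:-32])
        assert np.std(interior) < 1e-9

    def test_zero_tilt_is_identity(self):
        f = ComplexField(np.full((16, 16), 1 + 1j), 0.18, 666.0)
        rcfg = ReconstructionConfig(pixel_pitch_um=0.18, tilt_kx=0.0, tilt_ky=0.0)
        assert np.allclose(demodulate(f, rcfg).data, f.data)

    def test_opposite_tilts_cancel(self):
        rng = np.random.default_rng(4)
        f = ComplexField(rng.standard_normal((32, 32)) + 0j, 0.18, 666.0)
        c1 = ReconstructionConfig(pixel_pitch_um=0.18, tilt_kx=0.3, tilt_ky=-0.2)
        c2 = ReconstructionConfig(pixel_pitch_um=0.18, tilt_kx=-0.3, tilt_ky=0.2)
        out = demodulate(demodulate(f, c1), c2)
        assert np.allclose(out.data, f.data, atol=1e-12)


class TestFresnel:
    def _field(self, n=64):
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(rng.standard_normal((n, n)), 3) + 1j * gaussian_filter(
            rng.standard_normal((n, n)), 3
        )
        return ComplexField(data, 0.18, 666.0)

    def test_zero_distance_no_mask_is_identity(self):
        f = self._field()
        cfg = ReconstructionConfig(pixel_pitch_um=0.18, distance_um=0.0)
        assert np.array_equal(fresnel_reconstruct(f, cfg).data, f.data)

    @pytest.mark.parametrize("d", [250.0, 1000.0])
    def test_roundtrip_with_propagation(self, d):
        f = self._field()
        cfg = ReconstructionConfig(pixel_pitch_um=0.18, distance_um=d)
        back = fresnel_reconstruct(propagate(f, d), cfg)
        err = back.data - f.data
        rms = np.sqrt(np.mean(np.abs(err) ** 2) / np.mean(np.abs(f.data) ** 2))
        assert rms < 1e-6
        assert back.pixel_pitch_um == pytest.approx(0.18, rel=1e-12)

    def test_energy_conserved(self):
        f = self._field()
        cfg = ReconstructionConfig(pixel_pitch_um=0.18, distance_um=777.0)
        out = fresnel_reconstruct(f, cfg)
        assert out.energy() == pytest.approx(f.energy(), rel=1e-10)

    def test_phase_mask_applied_at_zero_distance(self):
        f = self._field()
        cfg = ReconstructionConfig(
            pixel_pitch_um=0.18, distance_um=0.0, phase_mask_D_um=5000.0
        )
        out = fresnel_reconstruct(f, cfg)
        assert np.allclose(np.abs(out.data), np.abs(f.data), atol=1e-12)
        assert not np.allclose(out.data, f.data)


class TestPhaseExtraction:
    def test_branch_conventions(self):
        data = np.array([[1 + 0j, 0 + 1j], [-1 + 0j, 0 - 1j]])
        pm = extract_phase(ComplexField(data, 0.18, 666.0))
        assert pm.values[0, 0] == 0.0
        assert pm.values[0, 1] == pytest.approx(np.pi / 2)
        assert pm.values[1, 0] == pytest.approx(np.pi)  # +pi, not -pi
        assert pm.values[1, 1] == pytest.approx(-np.pi / 2)

    def test_zero_magnitude_flagged(self):
        data = np.array([[0 + 0j, 1 + 0j], [1 + 1j, 2 + 0j]])
        pm = extract_phase(ComplexField(data, 0.18, 666.0))
        assert pm.values[0, 0] == 0.0
        assert pm.invalid[0, 0] and not pm.invalid[0, 1]

    def test_range_bound(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        pm = extract_phase(ComplexField(data, 0.18, 666.0))
        assert np.all(pm.values > -np.pi) and np.all(pm.values <= np.pi)


class TestUnwrap:
    def test_wrap_free_map_unchanged(self):
        y, x = np.mgrid[0:64, 0:64]
        smooth = 0.5 * np.sin(x / 20) + 0.3 * np.cos(y / 15)
        pm = PhaseMap(smooth, 0.18, 666.0)
        out = unwrap_phase(pm)
        offset = out.values[0, 0] - smooth[0, 0]
        assert np.allclose(out.values - offset, smooth, atol=1e-9)

    def test_wrapped_ramp_recovered_modulo_2pi(self):
        n = 128
        ramp = np.linspace(0, 3 * np.pi, n)[None, :] * np.ones((n, 1))
        wrapped = np.angle(np.exp(1j * ramp))
        out = unwrap_phase(PhaseMap(wrapped, 0.18, 666.0))
        resid = out.values - ramp
        assert np.allclose(resid, resid[0, 0], atol=1e-9)
        assert np.isclose(resid[0, 0] / (2 * np.pi), round(resid[0, 0] / (2 * np.pi)),
                          atol=1e-9)

    def test_unwrap_of_wrapped_smooth_field_constant_offset(self):
        rng = np.random.default_rng(6)
        from scipy.ndimage import gaussian_filter

        u = 4.0 * gaussian_filter(rng.standard_normal((96, 96)), 10)
        u *= 2.5 * np.pi / max(np.ptp(u), 1e-9)
        wrapped = np.angle(np.exp(1j * u))
        out = unwrap_phase(PhaseMap(wrapped, 0.18, 666.0))
        resid = out.values - u
        assert np.ptp(resid) < 1e-6


class TestBackgroundCompensation:
    def test_flat_zero_background_unchanged(self):
        vals = np.zeros((32, 32))
        vals[10:20, 10:20] = 1.0
        mask = vals == 0
        pm = PhaseMap(vals, 0.18, 666.0)
        out, _ = compensate_background(pm, mask, order=1)
        assert np.allclose(out.values, vals, atol=1e-12)

    def test_known_plane_exactly_removed(self):
        y, x = np.mgrid[0:48, 0:48]
        plane = 0.3 + 0.02 * x - 0.013 * y
        cell = np.zeros((48, 48))
        cell[20:30, 20:30] = 2.0
        mask = cell == 0
        pm = PhaseMap(plane + cell, 0.18, 666.0)
        out, _ = compensate_background(pm, mask, order=1)
        assert np.allclose(out.values[mask], 0.0, atol=1e-9)
        assert np.allclose(out.values[~mask], 2.0, atol=1e-9)

    def test_quadratic_background_removed_at_order_two(self):
        y, x = np.mgrid[0:48, 0:48]
        surf = 0.1 + 0.01 * x - 0.02 * y + 3e-4 * x * y - 2e-4 * x**2 + 1e-4 * y**2
        mask = np.ones((48, 48), bool)
        pm = PhaseMap(surf.copy(), 0.18, 666.0)
        out, _ = compensate_background(pm, mask, order=2)
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_empty_mask_rejected(self):
        pm = PhaseMap(np.zeros((16, 16)), 0.18, 666.0)
        with pytest.raises(ValueError):
            compensate_background(pm, np.zeros((16, 16), bool))


class TestPhaseToOpd:
    def test_two_pi_maps_to_wavelength(self):
        pm = PhaseMap(np.full((4, 4), 2 * np.pi), 0.18, 666.0)
        assert np.allclose(phase_to_opd(pm).data, 666.0)

    def test_zero_phase_zero_opd(self):
        pm = PhaseMap(np.zeros((4, 4)), 0.18, 666.0)
        assert np.allclose(phase_to_opd(pm).data, 0.0)


class TestEndToEnd:
    def test_noise_free_roundtrip_small(self, midsize_hologram):
        holo, scene, optics = midsize_hologram
        opd = reconstruct_hologram(holo)
        mask = scene > 20.0
        rms = np.sqrt(np.mean((opd.data - scene)[mask] ** 2))
        # twin-image leakage scales with grid separation; the 512^2 bound
        # is looser than the full-resolution (1024^2) sub-nanometre figure
        assert rms < 2.0

    def test_linearity_in_opd_scale(self, sealed_base):
        cfg = phantom.SceneConfig(grid_size=256, pixel_pitch_um=0.36, n_cells=1)
        scene = phantom.render_scene([sealed_base], cfg)
        optics = OpticalConfig(pixel_pitch_um=0.36)
        recons = []
        for alpha in (1.0, 0.4):
            obj = object_wave(alpha * scene, optics)
            ref = reference_wave(optics, scene.shape)
            holo = record_hologram(obj, ref, optics)
            recons.append(reconstruct_hologram(holo).data)
        mask = scene > 20.0
        resid = recons[1][mask] - 0.4 * recons[0][mask]
        assert np.sqrt(np.mean(resid**2)) < 1.0

    def test_translation_equivariance_whole_pixels(self, sealed_base):
        # shifts commensurate with the quarter-cycle carrier leave the
        # reference phase unchanged, so the reconstruction shifts exactly;
        # incommensurate shifts rotate the twin-leakage term and agree only
        # to the leakage scale
        cfg = phantom.SceneConfig(grid_size=256, pixel_pitch_um=0.36, n_cells=1)
        scene = phantom.render_scene([sealed_base], cfg)
        optics = OpticalConfig(pixel_pitch_um=0.36)
        ref = reference_wave(optics, scene.shape)
        holo0 = record_hologram(object_wave(scene, optics), ref, optics)
        filt = locate_sideband(holo0)
        rec0 = reconstruct_hologram(holo0, filt=filt).data
        for shift, tol in (((8, -12), 0.01), ((7, -12), 2.0)):
            shifted_scene = np.roll(scene, shift, axis=(0, 1))
            holo = record_hologram(object_wave(shifted_scene, optics), ref, optics)
            rec = reconstruct_hologram(holo, filt=filt).data
            moved = np.roll(rec0, shift, axis=(0, 1))
            mask = shifted_scene > 20.0
            assert np.sqrt(np.mean((rec - moved)[mask] ** 2)) < tol

    def test_twin_sideband_sign_resolved(self, sealed_base):
        # a reference tilted the "wrong" way puts the real image in the
        # negative half-plane; the non-negativity prior must still recover
        # a positive cell
        cfg = phantom.SceneConfig(grid_size=256, pixel_pitch_um=0.36, n_cells=1)
        scene = phantom.render_scene([sealed_base], cfg)
        lam_um = 0.666
        optics = OpticalConfig(
            pixel_pitch_um=0.36,
            tilt_kx=-lam_um / (4 * 0.36),
            tilt_ky=-lam_um / (4 * 0.36),
        )
        holo = record_hologram(
            object_wave(scene, optics), reference_wave(optics, scene.shape), optics
        )
        opd = reconstruct_hologram(holo)
        mask = scene > 20.0
        assert np.mean(opd.data[mask]) > 0
        # accuracy matches the normally oriented 256^2 reconstruction
        assert np.sqrt(np.mean((opd.data - scene)[mask] ** 2)) < 5.0
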