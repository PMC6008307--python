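"""Zernike basis, pupil phase and the PSF forward model."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phaseloc.optics import (OpticsConfig, PupilModel, crop_center,
                             phase_from_coeffs, psf_and_derivatives,
                             psf_model, psf_theoretical, zernike_basis,
                             zernike_nm)


def unit_disk_grid(n):
    # pixel-center (midpoint) sampling: halves the boundary bias of the
    # discrete disk integrals compared to endpoint-inclusive grids
    c = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    v, u = np.meshgrid(c, c, indexing="ij")
    return u, v


class TestZernikeBasis:
    def test_piston_is_constant(self):
        u, v = unit_disk_grid(64)
        z = zernike_basis(1, u, v)
        inside = u ** 2 + v ** 2 <= 1
        assert np.allclose(z[inside], z[inside][0])
        assert np.all(z[~inside] == 0.0)

    def test_noll_low_orders(self):
        # piston, tip/tilt, defocus, astigmatisms, comas, spherical
        assert zernike_nm(1) == (0, 0)
        assert zernike_nm(4) == (2, 0)
        assert {abs(zernike_nm(5)[1]), abs(zernike_nm(6)[1])} == {2}
        assert zernike_nm(11) == (4, 0)

    def test_orthogonality_brute_force(self):
        # discrete inner products over a fine disk grid vanish off-diagonal
        u, v = unit_disk_grid(512)
        maps = {j: zernike_basis(j, u, v) for j in range(1, 37)}
        norms = {j: float(np.sum(maps[j] * maps[j])) for j in maps}
        rng = np.random.default_rng(0)
        pairs = [(j, k) for j in range(1, 37) for k in range(j + 1, 37)]
        for j, k in [pairs[i] for i in rng.choice(len(pairs), 80, replace=False)]:
            ip = float(np.sum(maps[j] * maps[k]))
            assert abs(ip) < 1e-3 * np.sqrt(norms[j] * norms[k]), (j, k)

    def test_unit_rms_normalization(self):
        u, v = unit_disk_grid(1024)
        inside = u ** 2 + v ** 2 <= 1
        for j in (4, 5, 11):
            z = zernike_basis(j, u, v)
            rms = np.sqrt(np.mean(z[inside] ** 2))
            assert rms == pytest.approx(1.0, rel=5e-3)

    def test_defocus_rotation_invariant(self):
        u, v = unit_disk_grid(128)
        z = zernike_basis(4, u, v)
        assert np.allclose(z, np.rot90(z), atol=1e-12)

    @pytest.mark.parametrize("bad", [0, -3, 2.5])
    def test_invalid_index_rejected(self, bad):
        u, v = unit_disk_grid(8)
        with pytest.raises(ValueError):
            zernike_basis(bad, u, v)


class TestPhase:
    def test_zero_coeffs_zero_phase(self, optics64):
        pupil = PupilModel(optics=optics64, coeffs=np.zeros(12))
        assert np.all(phase_from_coeffs(pupil) == 0.0)

    def test_single_term_equals_basis(self, optics64):
        from phaseloc.optics import _grids
        coeffs = np.zeros(12)
        coeffs[0] = 1.0  # c4
        pupil = PupilModel(optics=optics64, coeffs=coeffs)
        g = _grids(optics64)
        expected = np.where(g.aperture, zernike_basis(4, g.u, g.v), 0.0)
        assert np.array_equal(phase_from_coeffs(pupil), expected)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_linearity(self, seed):
        optics = OpticsConfig(fft_size=32)
        rng = np.random.default_rng(seed)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        pa = phase_from_coeffs(PupilModel(optics=optics, coeffs=a))
        pb = phase_from_coeffs(PupilModel(optics=optics, coeffs=b))
        pab = phase_from_coeffs(PupilModel(optics=optics, coeffs=a + b))
        assert np.allclose(pa + pb, pab, atol=1e-9)


class TestPsfForwardModel:
    def test_in_focus_normalization_and_symmetry(self, flat_pupil):
        psf = psf_theoretical(flat_pupil, 0.0, 0.0, 0.0)
        assert psf.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(psf >= 0)
        c = flat_pupil.optics.fft_size // 2
        sub = psf[c - 12:c + 13, c - 12:c + 13]
        assert np.allclose(sub, sub[::-1, ::-1], atol=1e-9)

    def test_hermitian_symmetry_under_point_reflection(self, flat_pupil):
        a = psf_model(flat_pupil, 40.0, -25.0, 300.0)
        b = psf_model(flat_pupil, -40.0, 25.0, 300.0)
        c = flat_pupil.optics.fft_size // 2
        assert np.allclose(crop_center(a, 41),
                           crop_center(b, 41)[::-1, ::-1], atol=1e-9)

    def test_one_pixel_shift_translates_image(self, astig_pupil):
        p = astig_pupil.optics.pixel_size
        a = psf_model(astig_pupil, 0.0, 0.0, 200.0)
        b = psf_model(astig_pupil, p, 0.0, 200.0)
        # interior comparison: shifting x by one pitch moves one column
        assert np.allclose(b[:, 1:], a[:, :-1], rtol=1e-6, atol=1e-12)

    def test_axial_wavevector_at_origin(self, optics64):
        from phaseloc.optics import _grids
        g = _grids(optics64)
        c = optics64.fft_size // 2
        assert g.kz1[c, c] == pytest.approx(
            optics64.n_immersion / optics64.wavelength, rel=1e-12)

    def test_fft_matches_direct_dft(self, optics32):
        from phaseloc.optics import _pupil_u, _grids
        coeffs = np.array([0.2, -0.7, 0.4, 0.0, 0.1, 0.0, 0.0, 0.6, 0, 0, 0, 0])
        pupil = PupilModel(optics=optics32, coeffs=coeffs, blur_sigma=0.0)
        u = _pupil_u(pupil, 35.0, -10.0, 400.0)
        n = optics32.fft_size
        c = n // 2
        idx = np.arange(n) - c
        f = np.exp(-2j * np.pi * np.outer(idx, idx) / n)
        direct = f @ u @ f.T
        direct = (direct.real ** 2 + direct.imag ** 2) / _grids(optics32).norm ** 2
        fftpsf = psf_theoretical(pupil, 35.0, -10.0, 400.0)
        assert np.allclose(fftpsf, direct, rtol=1e-8, atol=1e-15)

    def test_nonnegative_for_random_pupils(self, optics32):
        rng = np.random.default_rng(7)
        for _ in range(100):
            coeffs = rng.uniform(-2.0, 2.0, size=12)
            pupil = PupilModel(optics=optics32, coeffs=coeffs, blur_sigma=0.0)
            psf = psf_theoretical(pupil, 0.0, 0.0, rng.uniform(-1500, 1500))
            assert psf.min() >= 0.0

    def test_blur_zero_is_identity(self, optics64):
        pupil = PupilModel(optics=optics64, coeffs=np.ones(12) * 0.3,
                           blur_sigma=0.0)
        assert np.array_equal(psf_model(pupil, 0, 0, 100.0),
                              psf_theoretical(pupil, 0, 0, 100.0))

    def test_blur_preserves_total_intensity(self, optics64):
        sharp = PupilModel(optics=optics64, coeffs=np.zeros(12), blur_sigma=0.0)
        blurred = dataclasses.replace(sharp, blur_sigma=0.7)
        a = psf_theoretical(sharp, 0, 0, 0.0)
        b = psf_model(blurred, 0, 0, 0.0)
        assert b.sum() == pytest.approx(a.sum(), rel=1e-3)

    def test_evanescent_cutoff_no_crash(self):
        # oil objective, aqueous sample: NA exceeds n_sample
        optics = OpticsConfig(na=1.49, n_immersion=1.518, n_sample=1.33,
                              fft_size=32)
        pupil = PupilModel(optics=optics, coeffs=np.zeros(12), blur_sigma=0.0)
        psf = psf_theoretical(pupil, 0, 0, 500.0)
        assert np.all(np.isfinite(psf)) and psf.sum() < 1.0

    def test_analytic_derivatives_match_finite_differences(self, optics64):
        pupil = PupilModel(optics=optics64,
                           coeffs=np.r_[0.1, 0.5, -0.3, np.zeros(9)],
                           blur_sigma=0.7)
        psf, d = psf_and_derivatives(pupil, 10.0, -20.0, 300.0,
                                     wrt=("x", "y", "z", "c5", "sigma"))
        for name, make in {
            "x": lambda e: psf_model(pupil, 10 + e, -20, 300),
            "y": lambda e: psf_model(pupil, 10, -20 + e, 300),
            "z": lambda e: psf_model(pupil, 10, -20, 300 + e),
            "c5": lambda e: psf_model(
                pupil.with_coeffs(pupil.coeffs + np.eye(12)[1] * e),
                10, -20, 300),
            "sigma": lambda e: psf_model(
                dataclasses.replace(pupil, blur_sigma=0.7 + e), 10, -20, 300),
        }.items():
            e = 1e-4 if name in ("c5", "sigma") else 1e-1
            fd = (make(e) - make(-e)) / (2 * e)
            scale = np.abs(fd).max()
            assert np.allclose(d[name], fd, atol=1e-5 * scale), name


class TestConfigAndSerialization:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            OpticsConfig(na=1.5, n_immersion=1.33)
        with pytest.raises(ValueError):
            OpticsConfig(fft_size=15)
        with pytest.raises(ValueError):
            PupilModel(coeffs=np.zeros(12), blur_sigma=-0.1)

    def test_json_round_trip(self, tmp_path, saddle_pupil):
        path = tmp_path / "pupil.json"
        saddle_pupil.save(path)
        back = PupilModel.load(path)
        assert back.optics == saddle_pupil.optics
        assert np.array_equal(back.coeffs, saddle_pupil.coeffs)
        assert back.blur_sigma == saddle_pupil.blur_sigma
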