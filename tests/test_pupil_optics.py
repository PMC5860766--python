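"""Forward-model physics: aperture, Zernikes, defocus, propagation, imaging."""

import numpy as np
import pytest

from aosim import (
    ObjectVolume,
    OpticalConfig,
    PhaseMap,
    central_second_moment,
    emission_image,
    estimate_T,
    make_pupil,
    propagate_to_volume,
    zernike_mode,
)
from aosim.errors import ConfigurationError, RangeError, ShapeError
from aosim.pupil_optics import (
    cfft2,
    defocus_phase,
    defocus_z4_coefficient,
    noll_to_nm,
    random_zernike_aberration,
    symmetric_z_planes,
)


class TestPupil:
    def test_disk_pixel_count_matches_lattice_oracle(self, cfg128, mask128):
        # brute-force count of lattice points inside the disk
        n = cfg128.grid_n
        r = cfg128.pupil_radius_px
        count = sum(
            1
            for i in range(n)
            for j in range(n)
            if (i - n // 2) ** 2 + (j - n // 2) ** 2 <= r**2
        )
        assert int(mask128.mask.sum()) == count
        assert abs(count - np.pi * r**2) < 4 * r  # Gauss-circle quantization

    def test_center_inside_corner_outside(self):
        cfg = OpticalConfig(grid_n=128, pupil_fill=1.0)
        mask = make_pupil(cfg)
        n = cfg.grid_n
        assert mask.mask[n // 2, n // 2]
        cfg_half = OpticalConfig(grid_n=128, pupil_fill=0.5)
        assert not make_pupil(cfg_half).mask[0, 0]

    def test_too_small_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            OpticalConfig(grid_n=32)
        with pytest.raises(ConfigurationError):
            make_pupil(OpticalConfig(grid_n=64, pupil_fill=0.1))


class TestZernike:
    @pytest.mark.parametrize(
        "noll,n,m", [(1, 0, 0), (2, 1, 1), (3, 1, -1), (4, 2, 0), (5, 2, -2), (11, 4, 0)]
    )
    def test_noll_index_mapping(self, noll, n, m):
        assert noll_to_nm(noll) == (n, m)

    def test_piston_is_constant(self, mask64):
        z1 = zernike_mode(1, mask64)
        assert np.allclose(z1.values, 1.0)

    def test_defocus_noll_normalization(self, mask128):
        # Z4 = sqrt(3)(2 rho^2 - 1): -sqrt(3) at center, +sqrt(3) at rho=1
        z4 = zernike_mode(4, mask128).values
        n = mask128.grid_n
        assert z4[n // 2, n // 2] == pytest.approx(-np.sqrt(3))
        edge = z4[n // 2, n // 2 + int(mask128.radius_px)]
        assert edge == pytest.approx(np.sqrt(3))

    def test_tip_is_odd_in_x(self, mask64):
        z2 = zernike_mode(2, mask64).values
        flipped = np.roll(z2[:, ::-1], 1, axis=1)  # mirror about the center pixel
        inside = mask64.mask
        assert np.allclose(z2[inside], -flipped[inside], atol=1e-12)


class TestDefocus:
    def test_zero_offset_and_linearity(self, cfg64, mask64):
        assert np.all(defocus_phase(0.0, cfg64, mask64).values == 0.0)
        d1 = defocus_phase(1.0, cfg64, mask64).values
        d2 = defocus_phase(2.0, cfg64, mask64).values
        assert np.allclose(d2, 2 * d1)
        assert defocus_z4_coefficient(0.0, cfg64) == 0.0

    def test_edge_phase_closed_form(self):
        cfg = OpticalConfig(
            wavelength_um=0.5, focal_length_mm=5.0, aperture_diameter_mm=5.0, grid_n=128
        )
        mask = make_pupil(cfg)
        dp = defocus_phase(1.0, cfg, mask)
        expected_peak = np.pi * (2500.0**2) * 1.0 / (0.5 * 5000.0**2)
        assert dp.values[mask.mask].max() == pytest.approx(expected_peak, rel=1e-6)


class TestPropagation:
    def test_parseval_energy(self, cfg64, mask64):
        psf = propagate_to_volume(PhaseMap(np.zeros((64, 64))), mask64, cfg64)
        assert psf.intensities[0].sum() == pytest.approx(float(mask64.mask.sum()), rel=1e-12)

    def test_energy_conserved_across_planes(self, cfg64, mask64):
        cfg = cfg64.with_z_planes(symmetric_z_planes(2.0, 5))
        psf = propagate_to_volume(PhaseMap(np.zeros((64, 64))), mask64, cfg)
        energies = psf.intensities.sum(axis=(1, 2))
        assert np.allclose(energies, energies[0], rtol=1e-3)

    def test_unaberrated_psf_is_sharpest(self, cfg64, mask64):
        sm0 = central_second_moment(
            propagate_to_volume(PhaseMap(np.zeros((64, 64))), mask64, cfg64).intensities[0]
        )
        for seed in (0, 1, 2):
            phi = random_zernike_aberration(mask64, seed=seed, rms_rad=1.0)
            sm = central_second_moment(
                propagate_to_volume(phi, mask64, cfg64).intensities[0]
            )
            assert sm > sm0

    def test_tip_translates_without_spreading(self, cfg64, mask64):
        # integer-pixel shift: Z2 coefficient c shifts the PSF by c*N/(pi*R) px
        n, r = cfg64.grid_n, mask64.radius_px
        c = np.pi * r / n  # 1-pixel shift
        sm0 = central_second_moment(
            propagate_to_volume(PhaseMap(np.zeros((n, n))), mask64, cfg64).intensities[0]
        )
        tip = PhaseMap(c * zernike_mode(2, mask64).values)
        sm = central_second_moment(propagate_to_volume(tip, mask64, cfg64).intensities[0])
        # tolerance covers tail wrap-around on the periodic grid
        assert sm == pytest.approx(sm0, rel=5e-3)

    def test_grid_mismatch_raises(self, cfg64, mask64):
        with pytest.raises(ShapeError):
            propagate_to_volume(PhaseMap(np.zeros((32, 32))), mask64, cfg64)

    def test_eq18_proportionality_single_plane(self, cfg128, mask128):
        """sm difference scales as c^2 * integral(|grad phi|^2) over a decade."""
        phi = random_zernike_aberration(mask128, seed=3, rms_rad=1.0)
        pupil = mask128.mask.astype(float)
        sm0 = central_second_moment(np.abs(cfft2(pupil)) ** 2)
        cs = np.array([0.25, 0.5, 1.0, 1.5, 2.0, 2.5])
        diffs = np.array(
            [
                central_second_moment(np.abs(cfft2(pupil * np.exp(1j * c * phi.values))) ** 2)
                - sm0
                for c in cs
            ]
        )
        slope = (diffs @ cs**2) / (cs**2 @ cs**2)
        assert np.max(np.abs(diffs - slope * cs**2) / diffs) < 0.02


class TestEmission:
    def test_linearity_in_object_is_exact(self, cfg64, mask64):
        cfg = cfg64.with_z_planes(symmetric_z_planes(1.0, 3))
        rng = np.random.default_rng(0)
        shape = (3, 64, 64)
        o1 = ObjectVolume(rng.uniform(0, 1, shape))
        o2 = ObjectVolume(rng.uniform(0, 1, shape))
        both = ObjectVolume(o1.concentration + o2.concentration)
        phi = random_zernike_aberration(mask64, seed=1, rms_rad=0.8)
        i1 = emission_image(phi, o1, cfg, mask=mask64).intensity
        i2 = emission_image(phi, o2, cfg, mask=mask64).intensity
        i12 = emission_image(phi, both, cfg, mask=mask64).intensity
        assert np.allclose(i1 + i2, i12, rtol=1e-10, atol=1e-10)

    def test_piston_invariance(self, cfg64, mask64):
        phi = random_zernike_aberration(mask64, seed=2, rms_rad=0.5)
        img = emission_image(phi, ObjectVolume.uniform(), cfg64, mask=mask64).intensity
        shifted = PhaseMap(phi.values + 1.234)
        img2 = emission_image(shifted, ObjectVolume.uniform(), cfg64, mask=mask64).intensity
        assert np.allclose(img, img2, rtol=1e-9, atol=1e-9 * img.max())

    def test_in_focus_uniform_image_radially_symmetric(self, cfg64, mask64):
        img = emission_image(
            PhaseMap(np.zeros((64, 64))), ObjectVolume.uniform(), cfg64, mask=mask64
        ).intensity
        mirrored = np.roll(img[::-1, ::-1], (1, 1), axis=(0, 1))
        assert np.allclose(img, mirrored, rtol=1e-8, atol=1e-8 * img.max())
        assert np.allclose(img, img.T, rtol=1e-8, atol=1e-8 * img.max())

    def test_asymmetric_z_planes_rejected(self, cfg64, mask64):
        cfg = cfg64.with_z_planes((0.0, 1.0))
        with pytest.raises(ConfigurationError):
            emission_image(
                PhaseMap(np.zeros((64, 64))), ObjectVolume.uniform(), cfg, mask=mask64
            )


class TestAxialRange:
    def test_threshold_is_bracketed_by_scan(self, cfg64, mask64):
        factor = 3.0
        T = estimate_T(cfg64, factor=factor, mask=mask64)
        pupil = mask64.mask.astype(float)

        def sm_at(z):
            ph = defocus_phase(z, cfg64, mask64).values
            return central_second_moment(np.abs(cfft2(pupil * np.exp(1j * ph))) ** 2)

        sm0 = sm_at(0.0)
        assert sm_at(T) >= factor * sm0
        assert sm_at(0.97 * T) < factor * sm0

    def test_monotone_in_factor_and_even_in_z(self, cfg64, mask64):
        t_small = estimate_T(cfg64, factor=2.0, mask=mask64)
        t_big = estimate_T(cfg64, factor=6.0, mask=mask64)
        assert t_small < t_big
        pupil = mask64.mask.astype(float)
        for z in (t_small, t_big):
            plus = defocus_phase(z, cfg64, mask64).values
            sp = central_second_moment(np.abs(cfft2(pupil * np.exp(1j * plus))) ** 2)
            sm = central_second_moment(np.abs(cfft2(pupil * np.exp(-1j * plus))) ** 2)
            assert sp == pytest.approx(sm, rel=1e-9)

    def test_unreachable_factor_reports_ratio(self, cfg64, mask64):
        cfg = cfg64.with_z_planes((-0.1, 0.0, 0.1))  # far too narrow a scan range
        with pytest.raises(RangeError) as err:
            estimate_T(cfg, factor=10.0, mask=mask64)
        assert np.isfinite(err.value.achieved_ratio)
        assert err.value.achieved_ratio < 10.0
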