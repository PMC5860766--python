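"""Gradient dot products, G matrices, SVD orthogonalization, displacement flags."""

import numpy as np
import pytest

from aosim import (
    GradientProductMatrix,
    InfluenceFunctionSet,
    PhaseMap,
    build_G,
    flag_displacement_modes,
    gradient_dot_direct,
    orthogonalize,
    synth_influence_functions,
    zernike_mode,
)
from aosim.errors import CalibrationError, UsageError
from aosim.modal_basis import gradient_norm, zernike_basis_on_dm, zernike_phase_basis
from aosim.pupil_optics import random_zernike_aberration


class TestGradientDot:
    def test_tip_self_product_is_4pi(self, mask128):
        # |grad Z2|^2 = 4 over the unit disk of area pi
        z2 = zernike_mode(2, mask128)
        assert gradient_dot_direct(z2, z2, mask128) == pytest.approx(4 * np.pi, rel=5e-3)

    def test_tip_tilt_orthogonal(self, mask64):
        z2, z3 = zernike_mode(2, mask64), zernike_mode(3, mask64)
        scale = gradient_dot_direct(z2, z2, mask64)
        assert abs(gradient_dot_direct(z2, z3, mask64)) < 1e-10 * scale

    def test_constant_map_has_zero_gradient(self, mask64):
        const = PhaseMap(np.full((64, 64), 2.5))
        phi = random_zernike_aberration(mask64, seed=0)
        assert gradient_dot_direct(phi, const, mask64) == 0.0

    def test_symmetry_and_bilinearity(self, mask64):
        p1 = random_zernike_aberration(mask64, seed=1)
        p2 = random_zernike_aberration(mask64, seed=2)
        d12 = gradient_dot_direct(p1, p2, mask64)
        assert d12 == gradient_dot_direct(p2, p1, mask64)
        assert gradient_dot_direct(2.5 * p1, p2, mask64) == pytest.approx(
            2.5 * d12, rel=1e-12
        )


class TestBuildG:
    def test_zernike_influences_give_diagonal_G(self, mask128):
        stack = np.stack(
            [zernike_mode(j, mask128).values for j in (2, 3, 4, 5)]
        )
        influence = InfluenceFunctionSet(stack)
        G = build_G(influence, mask128).G
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 5e-3 * np.diag(G).min()

    def test_duplicated_actuator_rank_deficient(self, small_dm, mask64):
        stack = small_dm.phases.copy()
        stack[3] = stack[2]
        G = build_G(InfluenceFunctionSet(stack), mask64).G
        evals = np.linalg.eigvalsh(G)
        assert evals.min() < 1e-10 * evals.max()

    def test_scaling_one_influence_scales_row_and_diagonal(self, small_dm, mask64):
        G0 = build_G(small_dm, mask64).G
        stack = small_dm.phases.copy()
        stack[5] *= 3.0
        G1 = build_G(InfluenceFunctionSet(stack), mask64).G
        assert G1[5, 5] == pytest.approx(9.0 * G0[5, 5], rel=1e-9)
        others = [i for i in range(small_dm.n_act) if i != 5]
        assert np.allclose(G1[5, others], 3.0 * G0[5, others], rtol=1e-9)

    def test_shack_hartmann_source_close_to_direct(self):
        from aosim import OpticalConfig, SHGeometry, make_pupil

        mask = make_pupil(OpticalConfig(grid_n=128, pupil_fill=1.0))
        dm = synth_influence_functions("square", 16, 0.3, mask, seed=7)
        Gd = build_G(dm, mask, "direct").G
        Gs = build_G(dm, mask, "shack_hartmann", sensor=SHGeometry(n_sub=16)).G
        # coarse sensor: require the same structure on the dominant entries
        big = np.abs(Gd) > 0.1 * np.abs(Gd).max()
        assert np.max(np.abs(Gs - Gd)[big] / np.abs(Gd)[big]) < 0.10


class TestOrthogonalize:
    def test_diagonal_G_gives_unit_modes(self):
        G = GradientProductMatrix(np.diag([4.0, 3.0, 2.0, 1.0]))
        basis = orthogonalize(G)
        assert np.allclose(np.abs(basis.coefficients), np.eye(4))
        assert np.all(np.diff(basis.singular_values) <= 0)

    def test_gram_of_realized_modes_is_diagonal(self, small_basis, mask64):
        ph = small_basis.mode_phases
        R = small_basis.n_modes
        gram = np.array(
            [
                [
                    gradient_dot_direct(PhaseMap(ph[a]), PhaseMap(ph[b]), mask64)
                    for b in range(R)
                ]
                for a in range(R)
            ]
        )
        off = np.abs(gram - np.diag(np.diag(gram))).max()
        assert off < 1e-6 * np.diag(gram).min()

    def test_pythagorean_gradient_additivity(self, small_basis, mask64):
        # for gradient-orthogonal g_i, g_j: |grad(g_i+g_j)|^2 integrates additively
        ph = small_basis.mode_phases
        gi, gj = PhaseMap(ph[1]), PhaseMap(ph[4])
        lhs = gradient_dot_direct(gi + gj, gi + gj, mask64)
        rhs = gradient_dot_direct(gi, gi, mask64) + gradient_dot_direct(gj, gj, mask64)
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_unit_gradient_normalization(self, small_basis, mask64):
        for k in range(small_basis.n_modes):
            assert gradient_norm(small_basis.phase_of(k), mask64) == pytest.approx(
                1.0, rel=1e-9
            )

    def test_rank_deficiency_drops_a_mode(self, small_dm, mask64):
        stack = small_dm.phases.copy()
        stack[3] = stack[2]
        G = build_G(InfluenceFunctionSet(stack), mask64)
        basis = orthogonalize(G, sv_cutoff_rel=1e-6)
        rank = np.linalg.matrix_rank(G.G, tol=1e-6 * np.abs(G.G).max())
        assert basis.n_modes == rank == small_dm.n_act - 1

    def test_all_below_cutoff_rejected(self):
        G = GradientProductMatrix(np.zeros((4, 4)))
        with pytest.raises(CalibrationError):
            orthogonalize(G)


class TestDisplacementFlags:
    def test_exact_zernike_influences_flagged(self, mask128):
        # a mutually gradient-orthogonal Zernike set (no cross-order couplings),
        # so the SVD modes stay pure and the displacement trio is unambiguous
        stack = np.stack(
            [zernike_mode(j, mask128).values for j in (2, 3, 4, 5, 6, 9)]
        )
        influence = InfluenceFunctionSet(stack)
        basis = orthogonalize(build_G(influence, mask128), influence=influence, mask=mask128)
        basis = flag_displacement_modes(basis, influence, mask128)
        assert int(basis.displacement_flags.sum()) == 3
        # flagged modes correlate perfectly with Z2, Z3, Z4
        for noll in (2, 3, 4):
            z = zernike_mode(noll, mask128)
            best = max(
                abs(gradient_dot_direct(basis.phase_of(k), z, mask128))
                / (gradient_norm(basis.phase_of(k), mask128) * gradient_norm(z, mask128))
                for k in np.flatnonzero(basis.displacement_flags)
            )
            assert best > 0.99

    def test_flags_on_synthetic_dm(self, small_basis):
        assert int(small_basis.displacement_flags.sum()) == 3
        assert len(small_basis.corrected_indices) == small_basis.n_modes - 3

    def test_too_few_modes_rejected(self, small_dm, mask64):
        G = build_G(small_dm, mask64)
        basis = orthogonalize(G, influence=small_dm, mask=mask64, max_modes=3)
        with pytest.raises(UsageError):
            flag_displacement_modes(basis, small_dm, mask64)

    def test_flags_invariant_under_sign_flip(self, small_dm, mask64):
        from dataclasses import replace

        G = build_G(small_dm, mask64)
        basis = orthogonalize(G, influence=small_dm, mask=mask64)
        flipped = replace(
            basis,
            coefficients=basis.coefficients * -1.0,
            mode_phases=basis.mode_phases * -1.0,
        )
        f1 = flag_displacement_modes(basis, small_dm, mask64).displacement_flags
        f2 = flag_displacement_modes(flipped, small_dm, mask64).displacement_flags
        assert np.array_equal(f1, f2)


class TestSyntheticDM:
    def test_deterministic_given_seed(self, mask64):
        a = synth_influence_functions("square", 16, 0.3, mask64, seed=3)
        b = synth_influence_functions("square", 16, 0.3, mask64, seed=3)
        assert np.array_equal(a.phases, b.phases)
        c = synth_influence_functions("square", 16, 0.3, mask64, seed=4)
        assert not np.array_equal(a.phases, c.phases)

    def test_hex_69_distinct_maps(self, mask64):
        infl = synth_influence_functions("hex", 69, 0.3, mask64, seed=0)
        assert infl.n_act == 69
        flat = infl.phases.reshape(69, -1)
        norms = np.linalg.norm(flat, axis=1)
        gram = (flat @ flat.T) / np.outer(norms, norms)
        assert np.all(gram[~np.eye(69, dtype=bool)] < 0.999)

    def test_zero_coupling_diagonal_dominant(self, mask64):
        infl = synth_influence_functions("square", 16, 0.0, mask64, seed=1)
        G = build_G(infl, mask64).G
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 0.05 * np.diag(G).min()


class TestCalibrationMethodAgreement:
    def test_direct_and_sensor_subspaces_align(self):
        """Leading mode subspaces from direct vs slope-sensor G agree closely."""
        from scipy.linalg import subspace_angles

        from aosim import OpticalConfig, SHGeometry, make_pupil

        mask = make_pupil(OpticalConfig(grid_n=128, pupil_fill=1.0))
        dm = synth_influence_functions("square", 16, 0.3, mask, seed=2)
        bd = orthogonalize(build_G(dm, mask, "direct"), max_modes=8)
        bs = orthogonalize(
            build_G(dm, mask, "shack_hartmann", sensor=SHGeometry(n_sub=16)),
            max_modes=8,
        )
        angles = subspace_angles(bd.coefficients.T, bs.coefficients.T)
        assert np.degrees(angles).max() < 2.0


class TestZernikeBases:
    def test_on_dm_rendering_close_to_target(self, mask64):
        infl = synth_influence_functions("square", 36, 0.3, mask64, seed=2)
        basis = zernike_basis_on_dm([5, 6, 7], infl, mask64)
        ideal = zernike_phase_basis([5, 6, 7], mask64)
        for k in range(3):
            g = PhaseMap(basis.mode_phases[k])
            z = PhaseMap(ideal.mode_phases[k])
            corr = gradient_dot_direct(g, z, mask64) / (
                gradient_norm(g, mask64) * gradient_norm(z, mask64)
            )
            # gradient-space correlation is a strict measure; a Gaussian-bump
            # mirror renders low-order shapes well but not perfectly
            assert abs(corr) > 0.75
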