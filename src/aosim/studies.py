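"""Reference simulation studies exercising the full method at desk scale.

These functions pin down the study conditions used by the validation tests
and the reproduction script: the optical system, the simulated mirrors, the
probe protocol and the problem sizes.  Every study is seeded and recomputes
its quantities from scratch by running the package.

Conditions (chosen once, as the package's reference configuration):

* optics: lambda = 0.52 um, f = 5 mm, D = 5 mm (paraxial NA 0.25);
  256^2 grid at pupil fill 0.5 for imaging studies, with the metric taken on
  the full camera frame (a sufficient detector; truncating the detection
  area is the method's own physical limit).
* axial range: 9 planes spanning the usable half-range (out-of-focus blur
  kept well inside the frame — see ``usable_axial_range``).
* low-order mirror: 43 Gaussian-influence actuators on a hexagonal lattice,
  nearest-neighbor coupling 0.3, calibrated to 35 retained modes = 32
  correction modes plus tip/tilt/defocus (the retained-mode count of a
  comparable low-order deformable mirror).
* probe amplitude 0.3 um of wavefront per unit-gradient-norm mode; mild test
  aberrations draw coefficients uniformly within 0.75x the probe, severe
  within 2x.
"""

from __future__ import annotations

import numpy as np

from .correction_loop import MicroscopeSystem, default_spot_offsets, run_correction
from .metric_engine import central_second_moment
from .modal_basis import (
    InfluenceFunctionSet,
    ModalBasis,
    build_G,
    flag_displacement_modes,
    gradient_dot_direct,
    orthogonalize,
    synth_influence_functions,
    zernike_basis_on_dm,
)
from .pupil_optics import (
    OpticalConfig,
    PhaseMap,
    PupilMask,
    cfft2,
    make_pupil,
    random_zernike_aberration,
    symmetric_z_planes,
    usable_axial_range,
)
from .shack_hartmann import SHGeometry, gradient_dot_sh, simulate_centroids
from .validation_suite import compare_bases, crossterm_scan, fit_crossterm, parameter_P

__all__ = [
    "reference_calibration",
    "budget_study",
    "separability_null_study",
    "proportionality_study",
    "gram_diagonality_study",
    "estimator_agreement_study",
    "recovery_study",
    "base_contrast_study",
]

PROBE_UM = 0.3
DM_COUPLING = 0.3
N_RETAINED_LOW_ORDER = 35          # 32 correction modes + 3 displacement modes
ZERNIKE_COMPARISON_NOLLS = (5, 6, 7, 8, 11, 12, 13, 16, 17, 22)
# representative reduced pair set: the azimuthally matched cross-order couples
# within 8th order (the canonically non-gradient-orthogonal pairs) plus
# neighboring uncoupled controls
ZERNIKE_COMPARISON_PAIRS = (
    (5, 13), (6, 12), (11, 22), (7, 17), (8, 16), (5, 6), (7, 8), (11, 12),
)


def _study_seed(seed: int, label: str) -> int:
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def reference_optics(grid_n: int = 256, pupil_fill: float = 0.5) -> OpticalConfig:
    return OpticalConfig(grid_n=grid_n, pupil_fill=pupil_fill)


def reference_calibration(
    seed: int,
    grid_n: int = 256,
    n_act: int = 43,
    layout: str = "hex",
    max_modes: int | None = N_RETAINED_LOW_ORDER,
) -> tuple[OpticalConfig, PupilMask, InfluenceFunctionSet, ModalBasis]:
    """Calibrated gradient-orthogonal basis on the reference system."""
    config = reference_optics(grid_n=grid_n)
    mask = make_pupil(config)
    influence = synth_influence_functions(
        layout, n_act, DM_COUPLING, mask, seed=_study_seed(seed, "dm")
    )
    basis = orthogonalize(
        build_G(influence, mask, method="direct"),
        influence=influence,
        mask=mask,
        max_modes=max_modes,
    )
    basis = flag_displacement_modes(basis, influence, mask)
    return config, mask, influence, basis


def _imaging_system(
    config: OpticalConfig,
    mask: PupilMask,
    basis: ModalBasis,
    injected: PhaseMap | None = None,
    n_planes: int = 9,
) -> MicroscopeSystem:
    half = usable_axial_range(config, window_px=config.grid_n // 2, mask=mask)
    cfg = config.with_z_planes(symmetric_z_planes(half, n_planes))
    return MicroscopeSystem(
        config=cfg, basis=basis, injected=injected, mask=mask, window=None
    )


def budget_study(seed: int) -> dict:
    """Measurement counts: 2N+1 per correction iteration and n^2 per scan.

    Runs the correction on a 128^2 system with 17 axial planes and a 3x3
    spot array (windowed extraction), N = 32 correction modes; and a 7x7
    cross-term scan on the same system.
    """
    config, mask, influence, basis = reference_calibration(seed, grid_n=128)
    half = usable_axial_range(config, window_px=64, mask=mask)
    cfg = config.with_z_planes(symmetric_z_planes(half, 17))
    injected = random_zernike_aberration(mask, seed=_study_seed(seed, "budget-ab"), rms_rad=0.5)
    system = MicroscopeSystem(
        config=cfg,
        basis=basis,
        injected=injected,
        mask=mask,
        window=64,
        spot_offsets=default_spot_offsets(128, n_side=3, spacing_px=28),
    )
    n_modes = len(basis.corrected_indices)
    result = run_correction(system, probe_amplitude_um=PROBE_UM, max_iter=1)
    scan = crossterm_scan(
        system, basis, basis.corrected_indices[0], basis.corrected_indices[1],
        amp_max_um=2 * PROBE_UM, n=7,
    )
    return {
        "n_correction_modes": n_modes,
        "correction_evaluations": result.measurement_count,
        "expected_correction_evaluations": 2 * n_modes + 1,
        "scan_evaluations": scan.n_evaluations,
        "n_spots": len(system.spot_offsets),
    }


def separability_null_study(seed: int) -> dict:
    """Parameter P of noise-free synthetic separable surfaces (theta = 0 and A1 = A2)."""
    from .validation_suite import CrossTermScan, _surface_model

    rng = np.random.default_rng(_study_seed(seed, "null"))
    amps = np.linspace(-0.6, 0.6, 7)
    ai, aj = np.meshgrid(amps, amps, indexing="ij")
    out = {}
    for label, (a1, a2, th) in {
        "theta_zero": (1.0 + rng.uniform(0, 2), 3.0 + rng.uniform(0, 2), 0.0),
        "equal_curvatures": (2.0 + rng.uniform(0, 1),) * 2 + (rng.uniform(-0.5, 0.5),),
    }.items():
        m = _surface_model(np.array([a1, a2, th, 5.0]), ai.ravel(), aj.ravel())
        scan = CrossTermScan(0, 1, amps, amps.copy(), m.reshape(7, 7), 49)
        out[label] = abs(parameter_P(fit_crossterm(scan)))
    return out


def proportionality_study(seed: int, grid_n: int = 256) -> dict:
    """Second-moment increase vs squared aberration amplitude, single plane.

    For a fixed smooth displacement-free aberration shape scaled by
    c in [0.25, 2] rad, regress sm(c) - sm(0) on c^2 and report the largest
    relative residual (the mean-square-gradient proportionality).
    """
    config = reference_optics(grid_n=grid_n)
    mask = make_pupil(config)
    phi = random_zernike_aberration(mask, seed=_study_seed(seed, "prop"), rms_rad=1.0)
    pupil = mask.mask.astype(float)
    sm0 = central_second_moment(np.abs(cfft2(pupil)) ** 2)
    cs = np.array([0.25, 0.35, 0.5, 0.7, 1.0, 1.4, 2.0])
    diffs = np.array(
        [
            central_second_moment(np.abs(cfft2(pupil * np.exp(1j * c * phi.values))) ** 2)
            - sm0
            for c in cs
        ]
    )
    slope = float(diffs @ cs**2 / (cs**2 @ cs**2))
    max_resid = float(np.max(np.abs(diffs - slope * cs**2) / diffs))
    return {"max_relative_residual": max_resid, "slope": slope, "n_scales": len(cs)}


def gram_diagonality_study(seed: int) -> dict:
    """Gradient-Gram diagonality of the basis from a 69-actuator mirror."""
    config = reference_optics(grid_n=128)
    mask = make_pupil(config)
    influence = synth_influence_functions(
        "hex", 69, DM_COUPLING, mask, seed=_study_seed(seed, "dm69")
    )
    basis = orthogonalize(
        build_G(influence, mask, method="direct"), influence=influence, mask=mask
    )
    R = basis.n_modes
    gram = np.empty((R, R))
    for a in range(R):
        for b in range(a, R):
            gram[a, b] = gram[b, a] = gradient_dot_direct(
                basis.phase_of(a), basis.phase_of(b), mask
            )
    off = np.abs(gram - np.diag(np.diag(gram))).max()
    return {
        "n_modes": R,
        "offdiag_over_diag": float(off / np.diag(gram).min()),
    }


def estimator_agreement_study(seed: int, n_aberrations: int = 20) -> dict:
    """Slope-sum estimator vs direct quadrature for random smooth aberrations.

    A 30x30 lenslet array over the full pupil (~750 valid subapertures, the
    low-order calibration scale) against the grid quadrature.
    """
    config = OpticalConfig(grid_n=256, pupil_fill=1.0)
    mask = make_pupil(config)
    geom = SHGeometry(n_sub=30)
    errs = []
    base = _study_seed(seed, "estimator")
    for k in range(n_aberrations):
        phi = random_zernike_aberration(mask, seed=base + k, rms_rad=1.0)
        direct = gradient_dot_direct(phi, phi, mask)
        c = simulate_centroids(phi, geom, mask)
        errs.append(abs(gradient_dot_sh(c, c) - direct) / direct)
    n_valid = len(simulate_centroids(phi, geom, mask).dx)
    return {
        "n_subapertures": n_valid,
        "max_relative_error": float(np.max(errs)),
        "median_relative_error": float(np.median(errs)),
    }


def recovery_study(seed: int, n_trials: int = 20) -> dict:
    """Correction quality on the noise-free reference system.

    Single-mode coefficient recovery; and gradient-norm reduction for
    ``n_trials`` random mode combinations at mild amplitude (one iteration)
    and severe amplitude (two iterations).
    """
    config, mask, influence, basis = reference_calibration(seed)
    ci = basis.corrected_indices
    rad = 2 * np.pi / config.wavelength_um
    phases = basis.mode_phases

    def correct(injected_coeffs: np.ndarray, iters: int):
        injected = PhaseMap(rad * np.tensordot(injected_coeffs, phases, axes=(0, 0)))
        system = _imaging_system(config, mask, basis, injected=injected)
        return run_correction(system, probe_amplitude_um=PROBE_UM, max_iter=iters)

    # single-mode recovery
    k = ci[3]
    coeffs = np.zeros(basis.n_modes)
    coeffs[k] = 0.2
    res = correct(coeffs, 1)
    single_err = abs(res.coefficients[k] + 0.2) / 0.2

    def reductions(scale: float, iters: int, label: str):
        out = []
        base = _study_seed(seed, label)
        for t in range(n_trials):
            rng = np.random.default_rng(base + t)
            c = np.zeros(basis.n_modes)
            c[ci] = rng.uniform(-scale, scale, len(ci))
            r = correct(c, iters)
            out.append(1.0 - r.residual_gradient_norm / r.initial_gradient_norm)
        return np.asarray(out)

    mild = reductions(0.75 * PROBE_UM, 1, "mild")
    severe = reductions(2.0 * PROBE_UM, 2, "severe")
    return {
        "single_mode_error_pct": float(100 * single_err),
        "mild_min_reduction_pct": float(100 * mild.min()),
        "mild_median_reduction_pct": float(100 * np.median(mild)),
        "severe_min_reduction_pct": float(100 * severe.min()),
        "severe_median_reduction_pct": float(100 * np.median(severe)),
        "n_trials": n_trials,
        "n_modes": len(ci),
    }


def base_contrast_study(seed: int) -> dict:
    """Parameter-P comparison: gradient-orthogonal basis vs Zernike-on-mirror.

    Both bases are realized on the same simulated 43-actuator mirror on a
    128^2 system; the Zernike side scans the representative reduced pair set
    (each azimuthally matched cross-order couple up to 8th order plus
    uncoupled controls), the orthogonal side all pairs of its first four
    correction modes.
    """
    config, mask, influence, basis = reference_calibration(seed, grid_n=128)
    zern = zernike_basis_on_dm(ZERNIKE_COMPARISON_NOLLS, influence, mask)
    system = _imaging_system(config, mask, basis)
    noll_pos = {n: i for i, n in enumerate(ZERNIKE_COMPARISON_NOLLS)}
    pairs_zern = [(noll_pos[a], noll_pos[b]) for a, b in ZERNIKE_COMPARISON_PAIRS]
    subset_orth = [int(k) for k in basis.corrected_indices[:4]]
    _, _, summary = compare_bases(
        system,
        basis,
        zern,
        amp_max_um=2 * PROBE_UM,
        subset_orth=subset_orth,
        subset_zern=list(range(len(ZERNIKE_COMPARISON_NOLLS))),
        pairs_zern=pairs_zern,
    )
    return {
        "median_abs_P_orthogonal": summary["gradient_orthogonal"]["median_abs_P"],
        "median_abs_P_zernike": summary["zernike"]["median_abs_P"],
        "max_abs_P_orthogonal": summary["gradient_orthogonal"]["max_abs_P"],
        "n_pairs_orthogonal": summary["gradient_orthogonal"]["n_pairs"],
        "n_pairs_zernike": summary["zernike"]["n_pairs"],
    }
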