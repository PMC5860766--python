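"""Modal 2N+1 aberration correction with per-mode quadratic fits.

One iteration measures the baseline metric M0 once, then M+ and M- for each
of the N corrected modes probed at +/- the probe amplitude; the vertex of the
parabola through the three points gives each mode's optimal coefficient, and
all corrections are applied jointly at the end of the iteration — exactly
2N+1 metric measurements.  The second moment is minimized, so only fits with
positive curvature are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CorrectionStalledError, QuadraticFitError, UsageError
from .metric_engine import MetricValue, extract_spots, metric_from_spots
from .modal_basis import ModalBasis
from .pupil_optics import (
    CameraImage,
    ObjectVolume,
    OpticalConfig,
    PhaseMap,
    PupilMask,
    emission_image,
    make_pupil,
)

__all__ = [
    "MicroscopeSystem",
    "MetricModel",
    "CorrectionResult",
    "probe_mode",
    "quadratic_optimum",
    "run_correction",
    "default_spot_offsets",
]


def default_spot_offsets(grid_n: int, n_side: int = 3, spacing_px: int | None = None):
    """Regular n_side x n_side grid of spot offsets (pixels) within the field."""
    if spacing_px is None:
        spacing_px = max(8, grid_n // 5)
    half = (n_side - 1) / 2.0
    return tuple(
        (int((i - half) * spacing_px), int((j - half) * spacing_px))
        for i in range(n_side)
        for j in range(n_side)
    )


@dataclass
class MicroscopeSystem:
    """Simulated microscope state: pupil, object, mirror basis and aberration.

    ``injected`` is the uncontrolled pupil aberration (radians).  The mirror
    correction is a coefficient vector over the basis modes in micrometres of
    wavefront; a coefficient c adds phase (2*pi*c/lambda) * g_k for the
    unit-gradient-norm mode shape g_k.  Every metric measurement increments
    ``metric_evaluations``.

    ``window=None`` computes the metric on the whole camera frame (a detector
    large enough to capture all spread light) and requires a single centered
    spot; truncating the detection area couples the modes, which is the
    method's own stated physical limit, so accuracy studies use the full
    frame while windowed extraction models realistic multi-spot detectors.
    """

    config: OpticalConfig
    basis: ModalBasis | None = None
    injected: PhaseMap | None = None
    obj: ObjectVolume = field(default_factory=ObjectVolume.uniform)
    mask: PupilMask | None = None
    spot_offsets: tuple[tuple[int, int], ...] | None = None
    window: int | None = 64
    min_separation: int = 8
    metric_evaluations: int = 0

    def __post_init__(self):
        if self.mask is None:
            self.mask = make_pupil(self.config)
        if self.spot_offsets is None:
            self.spot_offsets = ((0, 0),)
        n_corr = self.basis.n_modes if self.basis is not None else 0
        self.correction = np.zeros(n_corr)

    # -- state ------------------------------------------------------------- #

    def set_basis(self, basis: ModalBasis, reset_correction: bool = True) -> None:
        self.basis = basis
        if reset_correction or len(self.correction) != basis.n_modes:
            self.correction = np.zeros(basis.n_modes)

    def rad_per_um(self) -> float:
        return 2.0 * np.pi / self.config.wavelength_um

    def total_phase(self, extra_coeffs: np.ndarray | None = None) -> PhaseMap:
        """Pupil phase: injected aberration plus mirror correction (+probe)."""
        values = np.zeros((self.config.grid_n, self.config.grid_n))
        if self.injected is not None:
            values = values + self.injected.values
        coeffs = self.correction
        if extra_coeffs is not None:
            coeffs = coeffs + extra_coeffs
        if self.basis is not None and np.any(coeffs):
            values = values + self.rad_per_um() * np.tensordot(
                coeffs, self.basis.mode_phases, axes=(0, 0)
            )
        return PhaseMap(values)

    # -- imaging ----------------------------------------------------------- #

    def camera_image(
        self, extra_coeffs: np.ndarray | None = None, offset_px=(0, 0)
    ) -> CameraImage:
        return emission_image(
            self.total_phase(extra_coeffs),
            self.obj,
            self.config,
            excitation_offset_px=offset_px,
            mask=self.mask,
        )

    def spot_images(self, extra_coeffs: np.ndarray | None = None):
        """One camera image per excitation spot offset.

        With a uniform object a lateral shift of the excitation spot shifts
        the image rigidly, so the image is rendered once and rolled per spot.
        """
        if self.obj.is_uniform:
            base = self.camera_image(extra_coeffs)
            out = []
            for dy, dx in self.spot_offsets:
                arr = (
                    np.roll(base.intensity, (dy, dx), axis=(0, 1))
                    if (dy or dx)
                    else base.intensity
                )
                out.append(CameraImage(arr, base.pixel_um, {"offset_px": (dy, dx)}))
            return out
        return [
            self.camera_image(extra_coeffs, offset_px=off) for off in self.spot_offsets
        ]

    def measure_metric(self, extra_coeffs: np.ndarray | None = None) -> MetricValue:
        """Render spots, extract and average them, return the metric."""
        if self.window is None:
            if any(off != (0, 0) for off in self.spot_offsets):
                raise UsageError(
                    "full-frame metric (window=None) requires a single centered spot"
                )
            image = self.camera_image(extra_coeffs)
            self.metric_evaluations += 1
            from .metric_engine import central_second_moment

            return MetricValue(
                value=central_second_moment(image.intensity),
                n_spots=1,
                total_flux=float(image.intensity.sum()),
            )
        spots = []
        for image in self.spot_images(extra_coeffs):
            spots.extend(
                extract_spots(
                    image, 1, min_separation=self.min_separation, window=self.window
                )
            )
        self.metric_evaluations += 1
        return metric_from_spots(spots)

    def image_centroid(self, extra_coeffs: np.ndarray | None = None):
        from .metric_engine import first_moment

        return first_moment(self.camera_image(extra_coeffs).intensity)

    def residual_gradient_norm(self) -> float:
        """Gradient norm of injected-plus-correction (ground-truth diagnostic)."""
        from .modal_basis import gradient_norm as _gn

        return _gn(self.total_phase(), self.mask)


@dataclass(frozen=True)
class MetricModel:
    """Per-mode quadratic model of the metric around the current state."""

    M0: float
    curvatures: np.ndarray      # b_n per corrected mode (metric units / um^2)
    probe_amplitude: float      # um wavefront
    optima: np.ndarray          # fitted vertex per corrected mode (um)


@dataclass(frozen=True)
class CorrectionResult:
    coefficients: np.ndarray            # final correction vector (um) over all modes
    trace: list                         # dict rows: iter, mode, M0, Mplus, Mminus, a_opt, flag
    iterations: int
    measurement_count: int
    metric_per_iteration: tuple[float, ...]
    models: tuple[MetricModel, ...]
    residual_gradient_norm: float | None = None
    initial_gradient_norm: float | None = None


def probe_mode(
    system: MicroscopeSystem, basis: ModalBasis, mode: int, amplitude_um: float
) -> MetricValue:
    """Metric with one basis mode probed at a signed amplitude (um wavefront)."""
    if not 0 <= mode < basis.n_modes:
        raise UsageError(f"mode {mode} outside the retained basis")
    if basis.displacement_flags[mode]:
        raise UsageError(f"mode {mode} is a displacement mode and cannot be probed")
    if system.basis is not basis:
        system.set_basis(basis, reset_correction=False)
    extra = np.zeros(basis.n_modes)
    extra[mode] = amplitude_um
    return system.measure_metric(extra)


def quadratic_optimum(M0: float, Mplus: float, Mminus: float, a: float) -> float:
    """Vertex of the parabola through (-a, M-), (0, M0), (+a, M+).

    Returns the coefficient increment to ADD to the current state so the
    (minimized) metric decreases.  Raises :class:`QuadraticFitError` when the
    three points are not convex (curvature <= 0), in which case the caller
    should skip the mode.
    """
    if a == 0:
        raise UsageError("probe amplitude must be nonzero")
    denom = Mplus + Mminus - 2.0 * M0
    scale = max(abs(M0), abs(Mplus), abs(Mminus), 1e-300)
    if denom <= 1e-12 * scale:
        raise QuadraticFitError(
            f"non-convex three-point fit (curvature term {denom:.3e})"
        )
    return a * (Mminus - Mplus) / (2.0 * denom)


def run_correction(
    system: MicroscopeSystem,
    basis: ModalBasis | None = None,
    probe_amplitude_um: float = 0.3,
    max_iter: int = 1,
    clamp_factor: float | None = None,
) -> CorrectionResult:
    """Run the 2N+1 modal correction for ``max_iter`` iterations.

    Within one iteration all per-mode vertices are computed from the same
    frozen state (M0 measured once) and applied together at the end — the
    measurement budget is exactly 2N+1 per iteration.  Fits with non-positive
    curvature are skipped and logged.  ``clamp_factor`` optionally limits
    |a_opt| to ``clamp_factor * probe_amplitude_um`` to guard against wild
    extrapolation from noisy measurements.
    """
    if basis is not None:
        if system.basis is not basis:
            system.set_basis(basis, reset_correction=False)
    basis = system.basis
    if basis is None:
        raise UsageError("system has no modal basis")
    if probe_amplitude_um <= 0:
        raise UsageError("probe amplitude must be positive")
    corrected = basis.corrected_indices
    if corrected.size == 0:
        raise UsageError("basis has no correctable (non-displacement) modes")

    start_count = system.metric_evaluations
    initial_norm = (
        system.residual_gradient_norm() if system.injected is not None else None
    )
    trace: list[dict] = []
    metric_per_iter = []
    models = []
    for it in range(1, max_iter + 1):
        M0 = system.measure_metric().value
        metric_per_iter.append(M0)
        updates = np.zeros(basis.n_modes)
        curvatures = np.full(corrected.size, np.nan)
        optima = np.zeros(corrected.size)
        n_failed = 0
        for slot, k in enumerate(corrected):
            extra = np.zeros(basis.n_modes)
            extra[k] = probe_amplitude_um
            Mp = system.measure_metric(extra).value
            extra[k] = -probe_amplitude_um
            Mm = system.measure_metric(extra).value
            flag = "ok"
            try:
                a_opt = quadratic_optimum(M0, Mp, Mm, probe_amplitude_um)
                if clamp_factor is not None:
                    lim = clamp_factor * probe_amplitude_um
                    a_opt = float(np.clip(a_opt, -lim, lim))
                updates[k] = a_opt
                curvatures[slot] = (Mp + Mm - 2.0 * M0) / (2.0 * probe_amplitude_um**2)
                optima[slot] = a_opt
            except QuadraticFitError:
                a_opt = 0.0
                flag = "fit_failed"
                n_failed += 1
            trace.append(
                {
                    "iter": it,
                    "mode": int(k),
                    "M0": M0,
                    "Mplus": Mp,
                    "Mminus": Mm,
                    "a_opt": a_opt,
                    "flag": flag,
                }
            )
        if n_failed == corrected.size:
            raise CorrectionStalledError(
                f"all {corrected.size} mode fits failed in iteration {it}"
            )
        system.correction = system.correction + updates
        models.append(
            MetricModel(
                M0=M0,
                curvatures=curvatures,
                probe_amplitude=probe_amplitude_um,
                optima=optima,
            )
        )
    residual = system.residual_gradient_norm() if system.injected is not None else None
    return CorrectionResult(
        coefficients=system.correction.copy(),
        trace=trace,
        iterations=max_iter,
        measurement_count=system.metric_evaluations - start_count,
        metric_per_iteration=tuple(metric_per_iter),
        models=tuple(models),
        residual_gradient_norm=residual,
        initial_gradient_norm=initial_norm,
    )
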