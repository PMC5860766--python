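"""Scalar Fourier-optics forward model of an epifluorescence microscope.

The model treats the microscope as a telescope with an aberration phi(x, y)
in the shared pupil plane.  A coherent excitation field ``P * exp(i*phi)`` is
propagated to a stack of axial planes z' around focus by a centered discrete
Fourier transform with a quadratic defocus phase added per plane; fluorescence
emission at each plane is the excitation intensity times the fluorophore
concentration, and the camera image is the incoherent (intensity) convolution
of each emission plane with the coordinate-mirrored detection PSF of the
mirror plane -z', summed over planes.  Magnification is unity and the
excitation and emission wavelengths are identical (no Stokes shift).

Units: wavelengths and axial offsets in micrometres, lens focal length and
aperture diameter in millimetres, phases in radians.  Pupil coordinates are
normalized so the aperture edge sits at radius rho = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import factorial, pi, sqrt
from typing import Sequence

import numpy as np
from scipy import fft as sp_fft

from .errors import ConfigurationError, RangeError, ShapeError

__all__ = [
    "OpticalConfig",
    "PupilMask",
    "PhaseMap",
    "PSFStack",
    "ObjectVolume",
    "CameraImage",
    "make_pupil",
    "zernike_mode",
    "noll_to_nm",
    "defocus_phase",
    "defocus_z4_coefficient",
    "propagate_to_volume",
    "emission_image",
    "estimate_T",
    "usable_axial_range",
    "symmetric_z_planes",
    "random_zernike_aberration",
    "cfft2",
    "cifft2",
]

TWO_PI = 2.0 * pi


# --------------------------------------------------------------------------- #
# configuration and containers
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the simulated system.

    Parameters
    ----------
    wavelength_um : excitation/emission wavelength lambda (micrometres).
    focal_length_mm : objective focal length f (millimetres).
    aperture_diameter_mm : pupil diameter D (millimetres).
    grid_n : samples per side of the square pupil/image grid (even, >= 64).
    pupil_fill : fraction of the grid side spanned by the aperture, in (0, 1].
    z_planes_um : ordered axial offsets z' (micrometres) used for the
        3-D excitation stack and the plane sum of the camera image.  Must be
        symmetric about 0 for image formation.
    pixel_size_camera_um : physical camera pixel (informational; with unit
        magnification the image-plane sampling equals the object sampling).
    """

    wavelength_um: float = 0.52
    focal_length_mm: float = 5.0
    aperture_diameter_mm: float = 5.0
    grid_n: int = 128
    pupil_fill: float = 0.5
    z_planes_um: tuple[float, ...] = (0.0,)
    pixel_size_camera_um: float | None = None

    def __post_init__(self):
        if self.grid_n < 64 or self.grid_n % 2:
            raise ConfigurationError(
                f"grid_n must be even and >= 64, got {self.grid_n}"
            )
        if not (0.0 < self.pupil_fill <= 1.0):
            raise ConfigurationError(f"pupil_fill must be in (0, 1], got {self.pupil_fill}")
        for name in ("wavelength_um", "focal_length_mm", "aperture_diameter_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        object.__setattr__(self, "z_planes_um", tuple(float(z) for z in self.z_planes_um))

    @property
    def pupil_radius_px(self) -> float:
        """Aperture radius in grid pixels."""
        return self.pupil_fill * self.grid_n / 2.0

    @property
    def focal_length_um(self) -> float:
        return self.focal_length_mm * 1e3

    @property
    def aperture_diameter_um(self) -> float:
        return self.aperture_diameter_mm * 1e3

    @property
    def image_pixel_um(self) -> float:
        """Lateral sampling of the propagated field, lambda*f*fill/D."""
        return (
            self.wavelength_um
            * self.focal_length_um
            * self.pupil_fill
            / self.aperture_diameter_um
        )

    def with_z_planes(self, z_planes_um: Sequence[float]) -> "OpticalConfig":
        return replace(self, z_planes_um=tuple(float(z) for z in z_planes_um))


@dataclass(frozen=True)
class PupilMask:
    """Binary aperture on the grid plus normalized pupil coordinates.

    ``x``/``y`` are pixel-center coordinates normalized to the aperture radius
    (rho = 1 at the edge); the grid origin sits at index (grid_n//2, grid_n//2).
    """

    mask: np.ndarray           # bool (n, n)
    x: np.ndarray              # normalized column coordinate
    y: np.ndarray              # normalized row coordinate
    radius_px: float

    def __post_init__(self):
        if int(self.mask.sum()) == 0:
            raise ConfigurationError("pupil mask contains no points")

    @property
    def grid_n(self) -> int:
        return self.mask.shape[0]

    @property
    def pixel_area(self) -> float:
        """Area element of one grid pixel in normalized pupil units."""
        return (1.0 / self.radius_px) ** 2

    @property
    def area(self) -> float:
        """Quadrature area of the aperture in normalized units (~pi)."""
        return float(self.mask.sum()) * self.pixel_area

    @property
    def rho(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    @property
    def theta(self) -> np.ndarray:
        return np.arctan2(self.y, self.x)


@dataclass(frozen=True)
class PhaseMap:
    """Scalar pupil phase in radians, evaluated on the full grid.

    Values are physically meaningful only where the pupil mask is 1, but
    analytic generators (Zernike polynomials, Gaussian influence functions,
    defocus) extend smoothly across the whole grid so that finite-difference
    gradients are valid up to and including the mask boundary.
    """

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def grid_n(self) -> int:
        return self.values.shape[0]

    def __add__(self, other: "PhaseMap") -> "PhaseMap":
        return PhaseMap(self.values + other.values)

    def __mul__(self, scalar: float) -> "PhaseMap":
        return PhaseMap(self.values * float(scalar))

    __rmul__ = __mul__


@dataclass(frozen=True)
class PSFStack:
    """Complex excitation field E_o per axial plane."""

    fields: np.ndarray         # complex (nz, n, n)
    z_planes_um: tuple[float, ...]
    sampling_um: float         # lateral pixel pitch in object space

    @property
    def intensities(self) -> np.ndarray:
        return np.abs(self.fields) ** 2


@dataclass(frozen=True)
class ObjectVolume:
    """Nonnegative fluorophore concentration O(x', y', z').

    ``concentration is None`` denotes the uniform object O == 1 used
    throughout the validity argument of the method.
    """

    concentration: np.ndarray | None = None

    def __post_init__(self):
        if self.concentration is not None:
            arr = np.asarray(self.concentration, dtype=float)
            if np.any(arr < 0):
                raise ValueError("fluorophore concentration must be nonnegative")
            object.__setattr__(self, "concentration", arr)

    @property
    def is_uniform(self) -> bool:
        return self.concentration is None

    @classmethod
    def uniform(cls) -> "ObjectVolume":
        return cls(None)


@dataclass(frozen=True)
class CameraImage:
    """Nonnegative camera-plane intensity with provenance metadata."""

    intensity: np.ndarray
    pixel_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intensity, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("camera image must be finite")
        object.__setattr__(self, "intensity", np.clip(arr, 0.0, None))


# --------------------------------------------------------------------------- #
# centered transforms
# --------------------------------------------------------------------------- #


def cfft2(a: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D DFT: origin at grid index (n//2, n//2)."""
    return sp_fft.fftshift(sp_fft.fft2(sp_fft.ifftshift(a), norm="ortho"))


def cifft2(a: np.ndarray) -> np.ndarray:
    return sp_fft.fftshift(sp_fft.ifft2(sp_fft.ifftshift(a), norm="ortho"))


def _circular_convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Centered circular convolution of two real images."""
    fa = sp_fft.fft2(sp_fft.ifftshift(a))
    fb = sp_fft.fft2(sp_fft.ifftshift(b))
    return sp_fft.fftshift(sp_fft.ifft2(fa * fb).real)


def mirror_image(a: np.ndarray) -> np.ndarray:
    """Invert both coordinates about the grid center pixel (n//2, n//2)."""
    return np.roll(a[::-1, ::-1], (1, 1), axis=(0, 1))


# --------------------------------------------------------------------------- #
# pupil and aberrations
# --------------------------------------------------------------------------- #


def make_pupil(config: OpticalConfig) -> PupilMask:
    """Binary disk aperture of diameter ``pupil_fill * grid_n`` pixels."""
    n = config.grid_n
    radius_px = config.pupil_radius_px
    if radius_px < 8:
        raise ConfigurationError(
            f"pupil radius {radius_px:.1f} px is too small; increase grid_n or pupil_fill"
        )
    c = np.arange(n) - n // 2
    x = c[None, :] / radius_px
    y = c[:, None] / radius_px
    x = np.broadcast_to(x, (n, n)).copy()
    y = np.broadcast_to(y, (n, n)).copy()
    mask = (x**2 + y**2) <= 1.0
    return PupilMask(mask=mask, x=x, y=y, radius_px=radius_px)


def noll_to_nm(j: int) -> tuple[int, int]:
    """Map a Noll index j >= 1 to radial/azimuthal orders (n, m).

    The sign of m encodes the angular dependence: m >= 0 with even j is a
    cosine term, odd j a sine term (standard Noll convention).
    """
    if j < 1:
        raise ValueError("Noll index starts at 1")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        coef = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        )
        out += coef * rho ** (n - 2 * k)
    return out


def zernike_mode(noll_index: int, mask: PupilMask) -> PhaseMap:
    """Noll-normalized Zernike polynomial on normalized pupil coordinates.

    Evaluated on the full grid (the polynomial extends smoothly past rho = 1);
    restrict to ``mask.mask`` for any pupil integral.
    """
    n, m = noll_to_nm(noll_index)
    rho = mask.rho
    theta = mask.theta
    radial = _radial_poly(n, m, rho)
    if m == 0:
        values = sqrt(n + 1.0) * radial
    else:
        norm = sqrt(2.0 * (n + 1.0))
        angular = np.cos(abs(m) * theta) if noll_index % 2 == 0 else np.sin(abs(m) * theta)
        values = norm * radial * angular
    return PhaseMap(values)


def defocus_phase(z_offset_um: float, config: OpticalConfig, mask: PupilMask) -> PhaseMap:
    """Quadratic pupil phase pi*(x^2+y^2)*z'/(lambda*f^2) for an axial offset.

    The full quadratic (including its piston component) is returned; the
    piston is physically irrelevant to any intensity.  The equivalent Noll-Z4
    coefficient is available from :func:`defocus_z4_coefficient`.
    """
    r_um = config.aperture_diameter_um / 2.0
    x_um = mask.x * r_um
    y_um = mask.y * r_um
    values = (
        pi * (x_um**2 + y_um**2) * z_offset_um
        / (config.wavelength_um * config.focal_length_um**2)
    )
    return PhaseMap(values)


def defocus_z4_coefficient(z_offset_um: float, config: OpticalConfig) -> float:
    """Noll-Z4 coefficient (radians) of the quadratic defocus phase.

    pi*r^2*rho^2*z'/(lambda f^2) = a(z')*Z4 + piston with Z4 = sqrt(3)(2 rho^2 - 1),
    so a(z') = pi D^2 z' / (8 sqrt(3) lambda f^2).
    """
    d_um = config.aperture_diameter_um
    return (
        pi * d_um**2 * z_offset_um
        / (8.0 * sqrt(3.0) * config.wavelength_um * config.focal_length_um**2)
    )


# --------------------------------------------------------------------------- #
# propagation and image formation
# --------------------------------------------------------------------------- #


def propagate_to_volume(
    aberration: PhaseMap, mask: PupilMask, config: OpticalConfig
) -> PSFStack:
    """Coherent propagation of the aberrated pupil field to each z' plane.

    E_o(., ., z') is the centered unitary DFT of ``P * exp(i*(phi + phi_defocus(z')))``.
    The pure axial phase prefactor of the Fresnel propagator is dropped (it
    never affects an intensity).  Energy per plane equals the pupil energy.
    """
    if aberration.values.shape != mask.mask.shape:
        raise ShapeError(
            f"aberration grid {aberration.values.shape} != pupil grid {mask.mask.shape}"
        )
    n = mask.grid_n
    nz = len(config.z_planes_um)
    fields = np.empty((nz, n, n), dtype=complex)
    pupil = mask.mask.astype(float)
    for k, z in enumerate(config.z_planes_um):
        phase = aberration.values + defocus_phase(z, config, mask).values
        fields[k] = cfft2(pupil * np.exp(1j * phase))
    return PSFStack(fields=fields, z_planes_um=config.z_planes_um, sampling_um=config.image_pixel_um)


def _mirror_plane_indices(z_planes: Sequence[float]) -> list[int]:
    """Index of the -z plane for every z plane; error if not symmetric."""
    z = np.asarray(z_planes, dtype=float)
    scale = max(1.0, float(np.max(np.abs(z))))
    out = []
    for zi in z:
        j = int(np.argmin(np.abs(z + zi)))
        if abs(z[j] + zi) > 1e-9 * scale:
            raise ConfigurationError(
                "z_planes must be symmetric about 0 for image formation"
            )
        out.append(j)
    return out


def emission_image(
    excitation_aberration: PhaseMap,
    obj: ObjectVolume,
    config: OpticalConfig,
    excitation_offset_px: tuple[int, int] = (0, 0),
    mask: PupilMask | None = None,
    psf: PSFStack | None = None,
) -> CameraImage:
    """Camera image of fluorescence excited by one point-like spot.

    The excitation PSF (optionally shifted laterally by whole pixels) is
    multiplied by the fluorophore concentration per plane; each plane is then
    convolved with the coordinate-mirrored detection PSF of the mirror plane
    -z' (same pupil aberration, opposite propagation direction) and the plane
    images are averaged with uniform weights (equal excitation power per z').

    ``psf`` may carry a precomputed :func:`propagate_to_volume` result for the
    same aberration/config to avoid recomputation.
    """
    if mask is None:
        mask = make_pupil(config)
    if psf is None:
        psf = propagate_to_volume(excitation_aberration, mask, config)
    intensities = psf.intensities
    nz = intensities.shape[0]
    if not obj.is_uniform and obj.concentration.shape != intensities.shape:
        raise ShapeError(
            f"object volume {obj.concentration.shape} does not match "
            f"PSF stack {intensities.shape}"
        )
    mirror_idx = _mirror_plane_indices(psf.z_planes_um)
    dy, dx = int(excitation_offset_px[0]), int(excitation_offset_px[1])
    image = np.zeros_like(intensities[0])
    for k in range(nz):
        exc = intensities[k]
        if dy or dx:
            exc = np.roll(exc, (dy, dx), axis=(0, 1))
        if not obj.is_uniform:
            exc = exc * obj.concentration[k]
        det = mirror_image(intensities[mirror_idx[k]])
        image += _circular_convolve(exc, det)
    image /= nz
    return CameraImage(
        intensity=image,
        pixel_um=psf.sampling_um,
        meta={"offset_px": (dy, dx), "uniform_object": obj.is_uniform},
    )


# --------------------------------------------------------------------------- #
# axial range
# --------------------------------------------------------------------------- #


def _plane_second_moment(intensity: np.ndarray) -> float:
    from .metric_engine import central_second_moment

    return central_second_moment(intensity)


def estimate_T(
    config: OpticalConfig,
    factor: float,
    mask: PupilMask | None = None,
    z_max_um: float | None = None,
    n_scan: int = 160,
) -> float:
    """Axial half-range T: smallest z' with sm_o(0, z') >= factor * sm_o(0, 0).

    Scans the unaberrated defocused PSF over increasing z'.  If the config's
    ``z_planes_um`` span more than one plane, their positive values form the
    scan grid; otherwise a grid up to ``z_max_um`` (default: the offset giving
    ~40 rad of edge defocus) is used.
    """
    if factor <= 1.0:
        raise ValueError("factor must exceed 1")
    if mask is None:
        mask = make_pupil(config)
    r_um = config.aperture_diameter_um / 2.0
    z_unit = config.wavelength_um * config.focal_length_um**2 / (pi * r_um**2)

    zs = sorted({abs(z) for z in config.z_planes_um if z != 0.0})
    if not zs:
        if z_max_um is None:
            z_max_um = 40.0 * z_unit
        zs = list(np.linspace(z_max_um / n_scan, z_max_um, n_scan))

    pupil = mask.mask.astype(float)
    sm0 = _plane_second_moment(np.abs(cfft2(pupil)) ** 2)
    best_ratio = 1.0
    for z in zs:
        phase = defocus_phase(z, config, mask).values
        sm = _plane_second_moment(np.abs(cfft2(pupil * np.exp(1j * phase))) ** 2)
        ratio = sm / sm0
        best_ratio = max(best_ratio, ratio)
        if ratio >= factor:
            return float(z)
    raise RangeError(
        f"axial range insufficient: best sm ratio {best_ratio:.2f} < factor {factor}",
        achieved_ratio=best_ratio,
    )


def usable_axial_range(
    config: OpticalConfig,
    window_px: int,
    factor: float = 10.0,
    mask: PupilMask | None = None,
) -> float:
    """Default axial half-range T for the plane sum of the camera image.

    Two ceilings apply.  Physically, planes beyond the distance where the
    defocused second moment dwarfs the in-focus one contribute only dim,
    featureless background (:func:`estimate_T` with ``factor``).  Numerically,
    the windowed second-moment metric is only faithful while the out-of-focus
    light stays well inside the analysis window: the geometric excitation
    blur radius at z' is ``phi_edge(z') * grid_n / (pi * radius_px)`` pixels
    and detection doubles it, so the geometric camera blur diameter is kept
    within a quarter of the window (excitation blur radius <= window/16).
    The returned half-range is the smaller of the two.
    """
    r_um = config.aperture_diameter_um / 2.0
    phi_edge_per_um = pi * r_um**2 / (config.wavelength_um * config.focal_length_um**2)
    blur_px_per_um = phi_edge_per_um * config.grid_n / (pi * config.pupil_radius_px)
    t_window = (window_px / 16.0) / blur_px_per_um
    try:
        t_moment = estimate_T(config, factor=factor, mask=mask)
    except RangeError:
        t_moment = float("inf")
    return float(min(t_moment, t_window))


def symmetric_z_planes(half_range_um: float, n_planes: int = 33) -> tuple[float, ...]:
    """Odd count of planes uniformly spanning [-T, +T], including 0."""
    if n_planes % 2 == 0:
        raise ValueError("n_planes must be odd so that z'=0 is included")
    return tuple(np.linspace(-half_range_um, half_range_um, n_planes))


# --------------------------------------------------------------------------- #
# fixture aberrations
# --------------------------------------------------------------------------- #


def random_zernike_aberration(
    mask: PupilMask,
    seed: int,
    nolls: Sequence[int] = tuple(range(5, 16)),
    rms_rad: float = 1.0,
) -> PhaseMap:
    """Seeded random smooth aberration as a low-order Zernike combination.

    Displacement terms (Noll 1-4) are excluded by the default index range.
    Coefficients decay with index and the result is scaled to the requested
    RMS phase (piston removed) over the pupil.
    """
    rng = np.random.default_rng(seed)
    values = np.zeros_like(mask.x)
    for rank, j in enumerate(nolls):
        coef = rng.normal() / (1.0 + 0.15 * rank)
        values += coef * zernike_mode(j, mask).values
    inside = values[mask.mask]
    inside = inside - inside.mean()
    rms = float(np.sqrt(np.mean(inside**2)))
    if rms > 0:
        values *= rms_rad / rms
    return PhaseMap(values)
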