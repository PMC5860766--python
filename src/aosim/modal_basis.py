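"""Gradient-orthogonal modal bases for an adaptive optical element.

The gradient dot product phi1 .: phi2 = integral_P grad(phi1).grad(phi2) is
the bilinear form under which the second-moment metric is diagonal.  From the
influence functions of a deformable mirror a gradient-product matrix G is
assembled (directly, or through simulated Shack-Hartmann slopes); since G is
symmetric positive semi-definite, its SVD (equivalently eigendecomposition)
yields actuator-command combinations whose realized phases are pairwise
gradient-orthogonal.  The three modes most similar to tip, tilt and defocus
only displace or refocus the image and are flagged out of the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    AmbiguityError,
    CalibrationError,
    LayoutError,
    ShapeError,
    UsageError,
)
from .pupil_optics import PhaseMap, PupilMask, zernike_mode
from .shack_hartmann import SHGeometry, gradient_dot_sh, simulate_centroids

__all__ = [
    "InfluenceFunctionSet",
    "GradientProductMatrix",
    "ModalBasis",
    "gradient_dot_direct",
    "gradient_norm",
    "build_G",
    "orthogonalize",
    "flag_displacement_modes",
    "synth_influence_functions",
    "zernike_basis_on_dm",
    "zernike_phase_basis",
]


# --------------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class InfluenceFunctionSet:
    """Pupil phase response of each actuator to a unit command."""

    phases: np.ndarray                 # (n_act, n, n) radians per unit command
    centers: np.ndarray | None = None  # (n_act, 2) normalized actuator positions
    layout: str = "custom"

    def __post_init__(self):
        arr = np.asarray(self.phases, dtype=float)
        if arr.ndim != 3 or arr.shape[0] < 4:
            raise ValueError("need a (n_act >= 4, n, n) influence stack")
        if not np.all(np.isfinite(arr)):
            raise ValueError("influence functions must be finite")
        object.__setattr__(self, "phases", arr)

    @property
    def n_act(self) -> int:
        return self.phases.shape[0]


@dataclass(frozen=True)
class GradientProductMatrix:
    """Symmetric PSD matrix G_ij = phi_i .: phi_j of actuator influences."""

    G: np.ndarray
    source: str = "direct"

    def __post_init__(self):
        G = np.asarray(self.G, dtype=float)
        G = 0.5 * (G + G.T)
        scale = float(np.abs(G).max()) or 1.0
        eigmin = float(np.linalg.eigvalsh(G).min())
        if eigmin < -1e-8 * scale:
            raise ValueError(f"G is not positive semi-definite (eigmin {eigmin:.3e})")
        object.__setattr__(self, "G", G)

    @property
    def n_act(self) -> int:
        return self.G.shape[0]


@dataclass(frozen=True)
class ModalBasis:
    """Rows of actuator commands realizing gradient-orthogonal pupil modes."""

    coefficients: np.ndarray           # (n_modes, n_act)
    singular_values: np.ndarray        # (n_modes,)
    displacement_flags: np.ndarray     # (n_modes,) bool
    mode_phases: np.ndarray | None = None   # (n_modes, n, n) realized phases
    retained_indices: np.ndarray = field(default=None)  # into the original SVD order

    def __post_init__(self):
        if self.retained_indices is None:
            object.__setattr__(self, "retained_indices", np.arange(self.n_modes))

    @property
    def n_modes(self) -> int:
        return self.coefficients.shape[0]

    @property
    def corrected_indices(self) -> np.ndarray:
        """Modes used for aberration correction (displacement modes excluded)."""
        return np.flatnonzero(~self.displacement_flags)

    def phase_of(self, k: int) -> PhaseMap:
        if self.mode_phases is None:
            raise UsageError("basis carries no realized mode phases")
        return PhaseMap(self.mode_phases[k])


# --------------------------------------------------------------------------- #
# gradient quadrature
# --------------------------------------------------------------------------- #


def _gradients(values: np.ndarray, mask: PupilMask) -> tuple[np.ndarray, np.ndarray]:
    step = 1.0 / mask.radius_px
    gy, gx = np.gradient(values, step)
    return gx, gy


def _integration_domain(mask: PupilMask, exclude_boundary: bool) -> np.ndarray:
    if exclude_boundary:
        return ndimage.binary_erosion(mask.mask)
    return mask.mask


def gradient_dot_direct(
    phi1: PhaseMap,
    phi2: PhaseMap,
    mask: PupilMask,
    exclude_boundary: bool = False,
) -> float:
    """Quadrature of integral_P grad(phi1) . grad(phi2) by central differences.

    Phase maps generated by this package extend smoothly past the mask edge,
    so the default integrates over the full mask.  Set ``exclude_boundary``
    for maps defined only on the mask (drops the one-pixel boundary ring).
    """
    if phi1.values.shape != phi2.values.shape or phi1.values.shape != mask.mask.shape:
        raise ShapeError("phase maps and mask must share one grid")
    gx1, gy1 = _gradients(phi1.values, mask)
    gx2, gy2 = _gradients(phi2.values, mask)
    dom = _integration_domain(mask, exclude_boundary)
    return float(np.sum(gx1[dom] * gx2[dom] + gy1[dom] * gy2[dom]) * mask.pixel_area)


def gradient_norm(phi: PhaseMap, mask: PupilMask) -> float:
    """sqrt of the mean-square gradient integral of a phase map."""
    return float(np.sqrt(max(gradient_dot_direct(phi, phi, mask), 0.0)))


# --------------------------------------------------------------------------- #
# gradient-product matrix
# --------------------------------------------------------------------------- #


def build_G(
    influence: InfluenceFunctionSet,
    mask: PupilMask,
    method: str = "direct",
    sensor: SHGeometry | None = None,
) -> GradientProductMatrix:
    """G_ij = phi_i .: phi_j over all actuator influence pairs.

    ``method='direct'`` uses the grid quadrature; ``method='shack_hartmann'``
    estimates every product from simulated slope measurements (the
    subaperture slope-product sum), which is how a physical mirror is
    calibrated.
    """
    if method == "direct":
        gx = np.empty((influence.n_act, int(mask.mask.sum())))
        gy = np.empty_like(gx)
        dom = mask.mask
        for i in range(influence.n_act):
            gxi, gyi = _gradients(influence.phases[i], mask)
            gx[i] = gxi[dom]
            gy[i] = gyi[dom]
        G = (gx @ gx.T + gy @ gy.T) * mask.pixel_area
    elif method == "shack_hartmann":
        if sensor is None:
            raise UsageError("shack_hartmann method requires a sensor geometry")
        fields = [
            simulate_centroids(PhaseMap(influence.phases[i]), sensor, mask)
            for i in range(influence.n_act)
        ]
        n = influence.n_act
        G = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                G[i, j] = G[j, i] = gradient_dot_sh(fields[i], fields[j])
    else:
        raise UsageError(f"unknown method {method!r}")
    return GradientProductMatrix(G=0.5 * (G + G.T), source=method)


# --------------------------------------------------------------------------- #
# orthogonalization
# --------------------------------------------------------------------------- #


def _realize(coefficients: np.ndarray, influence: InfluenceFunctionSet) -> np.ndarray:
    return np.tensordot(coefficients, influence.phases, axes=(1, 0))


def orthogonalize(
    G: GradientProductMatrix,
    sv_cutoff_rel: float = 1e-3,
    influence: InfluenceFunctionSet | None = None,
    mask: PupilMask | None = None,
    normalize: bool = True,
    max_modes: int | None = None,
) -> ModalBasis:
    """SVD of G into a gradient-orthogonal actuator-command basis.

    G is symmetric PSD, so SVD coincides with the eigendecomposition up to
    ordering and signs; modes are eigenvectors sorted by decreasing singular
    value with the first nonzero component made positive (determinism across
    backends).  Modes below ``sv_cutoff_rel * max(singular values)`` are
    dropped.  When the influence set and mask are given, the realized pupil
    phase of each mode is cached and (by default) rescaled to unit gradient
    norm, integral |grad g|^2 = 1.
    """
    w, V = np.linalg.eigh(G.G)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    if w.max() <= 0.0:
        raise CalibrationError("gradient-product matrix carries no signal")
    keep = w >= sv_cutoff_rel * w.max()
    if max_modes is not None:
        keep &= np.arange(len(w)) < max_modes
    if not keep.any():
        raise CalibrationError("all modes fall below the singular-value cutoff")
    w = w[keep]
    coeffs = V[:, keep].T.copy()
    for row in coeffs:
        nz = np.flatnonzero(np.abs(row) > 1e-12)
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    phases = None
    if influence is not None:
        phases = _realize(coeffs, influence)
        if normalize:
            if mask is None:
                raise UsageError("normalization requires the pupil mask")
            for k in range(phases.shape[0]):
                norm = gradient_norm(PhaseMap(phases[k]), mask)
                if norm > 0:
                    coeffs[k] /= norm
                    phases[k] /= norm
    return ModalBasis(
        coefficients=coeffs,
        singular_values=w,
        displacement_flags=np.zeros(coeffs.shape[0], dtype=bool),
        mode_phases=phases,
        retained_indices=np.flatnonzero(keep),
    )


def flag_displacement_modes(
    basis: ModalBasis,
    influence: InfluenceFunctionSet,
    mask: PupilMask,
) -> ModalBasis:
    """Flag the modes most similar to tip, tilt and defocus (Noll 2, 3, 4).

    Similarity is the normalized gradient-space correlation
    |g .: Z| / sqrt((g .: g)(Z .: Z)); each displacement Zernike claims its
    best-matching distinct mode by greedy assignment on the correlation
    table (strongest pairing first).  The assignment is ambiguous — and an
    error carrying the table is raised — when a Zernike's assigned match
    falls below half its unconstrained best.  Flagged modes translate or
    refocus the image without degrading it and are excluded from correction.
    """
    if basis.n_modes < 4:
        raise UsageError("need at least 4 retained modes to spare 3 for displacement")
    phases = basis.mode_phases
    if phases is None:
        phases = _realize(basis.coefficients, influence)
    table = np.zeros((3, basis.n_modes))
    for zi, noll in enumerate((2, 3, 4)):
        z = zernike_mode(noll, mask)
        zz = gradient_dot_direct(z, z, mask)
        for k in range(basis.n_modes):
            g = PhaseMap(phases[k])
            gg = gradient_dot_direct(g, g, mask)
            if gg <= 0:
                continue
            table[zi, k] = abs(gradient_dot_direct(g, z, mask)) / np.sqrt(gg * zz)
    best_unconstrained = table.max(axis=1)
    work = table.copy()
    chosen = np.full(3, -1)
    for _ in range(3):
        zi, k = np.unravel_index(np.argmax(work), work.shape)
        chosen[zi] = k
        work[zi, :] = -1.0
        work[:, k] = -1.0
    for zi in range(3):
        if table[zi, chosen[zi]] < 0.5 * best_unconstrained[zi]:
            raise AmbiguityError(
                "displacement-mode assignment is ambiguous "
                f"(Zernike {zi + 2}: assigned correlation "
                f"{table[zi, chosen[zi]]:.3f} vs best {best_unconstrained[zi]:.3f})",
                correlation_table=table,
            )
    flags = np.zeros(basis.n_modes, dtype=bool)
    flags[chosen] = True
    return replace(basis, displacement_flags=flags, mode_phases=phases)


# --------------------------------------------------------------------------- #
# synthetic deformable mirrors
# --------------------------------------------------------------------------- #


def _lattice_sites(layout: str, n_act: int, r_act: float) -> tuple[np.ndarray, float]:
    """The n_act lattice sites nearest the axis, plus the lattice pitch."""
    if layout == "square":
        d = r_act * np.sqrt(np.pi / n_act)
        k = int(np.ceil(2.0 * r_act / d)) + 2
        idx = np.arange(-k, k + 1)
        xs, ys = np.meshgrid(idx * d, idx * d)
    elif layout == "hex":
        d = r_act * np.sqrt(2.0 * np.pi / (np.sqrt(3.0) * n_act))
        k = int(np.ceil(2.0 * r_act / d)) + 2
        rows = np.arange(-k, k + 1)
        xs_list, ys_list = [], []
        for r in rows:
            offset = 0.5 * d if r % 2 else 0.0
            xs_list.append(np.arange(-k, k + 1) * d + offset)
            ys_list.append(np.full(2 * k + 1, r * d * np.sqrt(3.0) / 2.0))
        xs = np.concatenate(xs_list)
        ys = np.concatenate(ys_list)
    else:
        raise UsageError(f"unknown layout {layout!r}")
    pts = np.column_stack([np.ravel(xs), np.ravel(ys)])
    dist = np.hypot(pts[:, 0], pts[:, 1])
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.lexsort((ang, np.round(dist, 9)))
    pts = pts[order]
    if len(pts) < n_act:
        raise LayoutError("lattice too small for the requested actuator count")
    return pts[:n_act], d


def synth_influence_functions(
    layout: str,
    n_act: int,
    coupling: float,
    mask: PupilMask,
    seed: int,
    r_act: float = 1.08,
) -> InfluenceFunctionSet:
    """Gaussian-bump influence functions on a square or hexagonal lattice.

    Emulates a membrane/piezo deformable mirror slightly larger than the
    pupil: each actuator raises a Gaussian phase bump whose value at the
    nearest-neighbor center equals ``coupling``.  A small seeded jitter on
    gains and positions breaks the lattice symmetry (real mirrors are never
    perfectly symmetric), which also keeps the SVD mode ordering stable.
    """
    if not (0.0 <= coupling < 1.0):
        raise UsageError("coupling must be in [0, 1)")
    centers, d = _lattice_sites(layout, n_act, r_act)
    rng = np.random.default_rng(seed)
    centers = centers + rng.normal(0.0, 0.015 * d, size=centers.shape)
    gains = 1.0 + rng.normal(0.0, 0.02, size=n_act)
    if np.any(np.hypot(centers[:, 0], centers[:, 1]) > 1.2 * r_act):
        raise LayoutError("actuator centers fall outside the inflated pupil")
    if coupling > 1e-6:
        sigma = d / np.sqrt(2.0 * np.log(1.0 / coupling))
    else:
        sigma = d / 6.0   # near-disjoint bumps
    phases = np.empty((n_act, mask.grid_n, mask.grid_n))
    for i, (cx, cy) in enumerate(centers):
        phases[i] = gains[i] * np.exp(
            -((mask.x - cx) ** 2 + (mask.y - cy) ** 2) / (2.0 * sigma**2)
        )
    return InfluenceFunctionSet(phases=phases, centers=centers, layout=layout)


# --------------------------------------------------------------------------- #
# Zernike comparison bases
# --------------------------------------------------------------------------- #


def zernike_phase_basis(
    nolls: Sequence[int], mask: PupilMask, normalize: bool = True
) -> ModalBasis:
    """Ideal Zernike phases as a modal basis (no mirror in the loop)."""
    phases = np.stack([zernike_mode(j, mask).values for j in nolls])
    coeffs = np.eye(len(nolls))
    if normalize:
        for k in range(phases.shape[0]):
            norm = gradient_norm(PhaseMap(phases[k]), mask)
            if norm > 0:
                phases[k] /= norm
                coeffs[k] /= norm
    return ModalBasis(
        coefficients=coeffs,
        singular_values=np.ones(len(nolls)),
        displacement_flags=np.zeros(len(nolls), dtype=bool),
        mode_phases=phases,
    )


def zernike_basis_on_dm(
    nolls: Sequence[int],
    influence: InfluenceFunctionSet,
    mask: PupilMask,
    normalize: bool = True,
) -> ModalBasis:
    """Zernike targets rendered by the mirror via least-squares command fits.

    This is the non-orthogonalized comparison basis: the mirror's imperfect
    rendering couples the modes under the gradient product even when the
    target Zernikes would not.
    """
    dom = mask.mask
    A = influence.phases[:, dom].T          # (n_px, n_act)
    coeffs = np.empty((len(nolls), influence.n_act))
    for k, j in enumerate(nolls):
        target = zernike_mode(j, mask).values[dom]
        target = target - target.mean()
        sol, *_ = np.linalg.lstsq(A - A.mean(axis=0), target, rcond=None)
        coeffs[k] = sol
    phases = _realize(coeffs, influence)
    if normalize:
        for k in range(phases.shape[0]):
            norm = gradient_norm(PhaseMap(phases[k]), mask)
            if norm > 0:
                phases[k] /= norm
                coeffs[k] /= norm
    return ModalBasis(
        coefficients=coeffs,
        singular_values=np.ones(len(nolls)),
        displacement_flags=np.zeros(len(nolls), dtype=bool),
        mode_phases=phases,
    )
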