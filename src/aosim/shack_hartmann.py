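"""Idealized Shack-Hartmann slope sensor and the slope-based gradient product.

The sensor reports, per subaperture, the mean wavefront slope over the
subaperture interior — the quantity a calibrated lenslet centroid measures —
with no lenslet diffraction or photon noise.  The pairwise sum of slope
products over subapertures estimates the pupil gradient dot product
integral(grad(phi1) . grad(phi2)); the absolute scale used here is the
area-weighted mean slope product times the pupil area, so a constant slope s
yields exactly s^2 * (pupil area), matching the direct quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ResolutionError, ShapeError
from .pupil_optics import PhaseMap, PupilMask

__all__ = ["SHGeometry", "CentroidField", "simulate_centroids", "gradient_dot_sh"]


@dataclass(frozen=True)
class SHGeometry:
    """Square lenslet grid covering the pupil bounding box [-1, 1]^2.

    ``n_sub`` lenslets per side, each of pitch 2/n_sub in normalized pupil
    units.  A subaperture is valid when more than ``min_coverage`` of its grid
    pixels fall inside the pupil; the default accepts any overlap, because the
    idealized sensor reports exact mean slopes even over a partly covered
    lenslet and each subaperture is weighted by its covered area (the
    gradient energy of pupil aberrations concentrates at the aperture edge,
    so discarding partly covered subapertures biases the estimator low).  Set
    it to e.g. 0.5 to emulate a real sensor's validity rule.
    ``lenslet_focal_mm`` only matters for converting physical centroid
    displacements and is informational here.
    """

    n_sub: int
    lenslet_focal_mm: float = 5.0
    min_coverage: float = 0.0

    def __post_init__(self):
        if self.n_sub < 2:
            raise ValueError("need at least 2 subapertures per side")
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in [0, 1]")

    @property
    def pitch(self) -> float:
        return 2.0 / self.n_sub


@dataclass(frozen=True)
class CentroidField:
    """Per-valid-subaperture mean slopes (radian per normalized pupil unit)."""

    dx: np.ndarray              # slope along x (columns)
    dy: np.ndarray              # slope along y (rows)
    weights: np.ndarray         # covered pupil area per subaperture
    positions: np.ndarray       # (n_valid, 2) subaperture centers (x, y)
    geometry: SHGeometry
    mask_area: float            # total pupil quadrature area

    def __post_init__(self):
        if not (len(self.dx) == len(self.dy) == len(self.weights) == len(self.positions)):
            raise ValueError("inconsistent centroid field lengths")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("centroid displacements must be finite")


def _subaperture_selections(geom: SHGeometry, mask: PupilMask):
    """Boolean pixel selections, centers and covered areas of valid subapertures."""
    n = mask.grid_n
    px_per_sub = geom.pitch * mask.radius_px
    if px_per_sub < 4:
        raise ResolutionError(
            f"{px_per_sub:.1f} grid pixels per subaperture; need >= 4 "
            "(refine the grid or coarsen the lenslet array)"
        )
    # subaperture index of every grid pixel along each axis
    coord = (np.arange(n) - n // 2) / mask.radius_px      # normalized pixel centers
    sub_idx = np.floor((coord + 1.0) / geom.pitch).astype(int)
    in_box = (sub_idx >= 0) & (sub_idx < geom.n_sub)
    selections = []
    full_count = px_per_sub**2
    for iy in range(geom.n_sub):
        rows = in_box & (sub_idx == iy)
        if not rows.any():
            continue
        for ix in range(geom.n_sub):
            cols = in_box & (sub_idx == ix)
            if not cols.any():
                continue
            sel = np.logical_and.outer(rows, cols) & mask.mask
            covered = int(sel.sum())
            if covered == 0 or covered / full_count < geom.min_coverage:
                continue
            cx = -1.0 + (ix + 0.5) * geom.pitch
            cy = -1.0 + (iy + 0.5) * geom.pitch
            selections.append((sel, (cx, cy), covered * mask.pixel_area))
    if len(selections) < 4:
        raise ResolutionError("fewer than 4 valid subapertures over the pupil")
    return selections


def simulate_centroids(phi: PhaseMap, geom: SHGeometry, mask: PupilMask) -> CentroidField:
    """Mean finite-difference phase slope per valid subaperture."""
    if phi.values.shape != mask.mask.shape:
        raise ShapeError("phase map and pupil mask grids differ")
    step = 1.0 / mask.radius_px
    gy, gx = np.gradient(phi.values, step)
    selections = _subaperture_selections(geom, mask)
    dx = np.array([gx[sel].mean() for sel, _, _ in selections])
    dy = np.array([gy[sel].mean() for sel, _, _ in selections])
    weights = np.array([w for _, _, w in selections])
    positions = np.array([c for _, c, _ in selections])
    return CentroidField(
        dx=dx, dy=dy, weights=weights, positions=positions,
        geometry=geom, mask_area=mask.area,
    )


def gradient_dot_sh(c1: CentroidField, c2: CentroidField) -> float:
    """Slope-product estimate of integral(grad(phi1) . grad(phi2)).

    Computed as the covered-area-weighted mean of dx1*dx2 + dy1*dy2 over
    valid subapertures, rescaled by the pupil area so the estimate shares the
    units and scale of the direct quadrature.
    """
    if c1.geometry != c2.geometry or len(c1.dx) != len(c2.dx):
        raise ShapeError("centroid fields come from different sensor geometries")
    w = c1.weights
    num = float(np.sum(w * (c1.dx * c2.dx + c1.dy * c2.dy)))
    return num / float(np.sum(w)) * c1.mask_area
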