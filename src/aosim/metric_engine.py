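"""Image moments, spot extraction and the averaged second-moment metric.

The sharpness metric of the whole method is the central second moment of the
pixel-wise average of background-subtracted crops around the brightest
fluorescence spots: aberrations spread excitation and emission light, which
raises the second moment, so the metric is minimized by a flat wavefront.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import peak_local_max

from .errors import DegenerateInputError, DetectionError
from .pupil_optics import CameraImage

__all__ = [
    "SpotImage",
    "MetricValue",
    "first_moment",
    "central_second_moment",
    "extract_spots",
    "metric_from_spots",
]


@dataclass(frozen=True)
class SpotImage:
    """Background-subtracted crop around one detected spot.

    ``center_px`` is the (row, col) position of the spot maximum in the parent
    image; ``source_index`` orders spots by brightness rank.
    """

    intensity: np.ndarray
    center_px: tuple[int, int]
    source_index: int


@dataclass(frozen=True)
class MetricValue:
    """Second moment (pixel^2) of an averaged spot image."""

    value: float
    n_spots: int
    total_flux: float

    def __post_init__(self):
        if self.value < 0 or self.n_spots < 1:
            raise ValueError("invalid metric value")


def first_moment(image: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted centroid (row, col) in pixel coordinates."""
    image = np.asarray(image, dtype=float)
    total = image.sum()
    if total <= 0:
        raise DegenerateInputError("first moment of an all-zero image is undefined")
    rows = np.arange(image.shape[0], dtype=float)
    cols = np.arange(image.shape[1], dtype=float)
    m_r = float((image.sum(axis=1) * rows).sum() / total)
    m_c = float((image.sum(axis=0) * cols).sum() / total)
    return m_r, m_c


def central_second_moment(image: np.ndarray) -> float:
    """Flux-normalized mean squared distance from the centroid (pixel^2)."""
    image = np.asarray(image, dtype=float)
    total = image.sum()
    if total <= 0:
        raise DegenerateInputError("second moment of an all-zero image is undefined")
    m_r, m_c = first_moment(image)
    rows = np.arange(image.shape[0], dtype=float) - m_r
    cols = np.arange(image.shape[1], dtype=float) - m_c
    r2 = rows[:, None] ** 2 + cols[None, :] ** 2
    return float((image * r2).sum() / total)


def _edge_flux_fraction(crop: np.ndarray, ring: int = 2) -> float:
    total = crop.sum()
    if total <= 0:
        return 0.0
    inner = crop[ring:-ring, ring:-ring].sum()
    return float(1.0 - inner / total)


def extract_spots(
    image: CameraImage | np.ndarray,
    n_spots: int,
    min_separation: int = 8,
    window: int = 64,
    edge_flux_warn: float = 0.01,
) -> list[SpotImage]:
    """Crop the ``n_spots`` brightest well-separated local maxima.

    Candidates are local maxima at least ``min_separation`` pixels apart whose
    ``window``-sized crop lies fully inside the image; ties break by
    (intensity desc, row, col) for determinism.  Each crop is median
    background-subtracted with negative residuals clipped to zero.  A warning
    is issued when more than ``edge_flux_warn`` of a crop's flux falls in its
    outer two-pixel ring (light spread close to the window limit).
    """
    arr = image.intensity if isinstance(image, CameraImage) else np.asarray(image, dtype=float)
    if window % 2:
        raise ValueError("window must be even")
    half = window // 2
    peaks = peak_local_max(arr, min_distance=int(min_separation), threshold_rel=0.0)
    candidates = []
    for r, c in peaks:
        if half <= r <= arr.shape[0] - half and half <= c <= arr.shape[1] - half:
            candidates.append((-arr[r, c], int(r), int(c)))
    candidates.sort()
    if len(candidates) < n_spots:
        raise DetectionError(
            f"found {len(candidates)} spot candidates, need {n_spots}",
            found=len(candidates),
        )
    spots = []
    for idx, (_, r, c) in enumerate(candidates[:n_spots]):
        crop = arr[r - half : r + half, c - half : c + half].astype(float).copy()
        crop -= np.median(crop)
        np.clip(crop, 0.0, None, out=crop)
        if _edge_flux_fraction(crop) > edge_flux_warn:
            warnings.warn(
                f"spot at ({r}, {c}): >{edge_flux_warn:.0%} of flux in the outer "
                "2-pixel ring; the window may be too small for this aberration",
                stacklevel=2,
            )
        spots.append(SpotImage(intensity=crop, center_px=(r, c), source_index=idx))
    return spots


def metric_from_spots(spots: list[SpotImage], average_image: bool = True) -> MetricValue:
    """Second moment of the pixel-wise average of the spot crops.

    With ``average_image=False`` the mean of per-spot second moments is
    returned instead; the two coincide for equal-flux identical spots but
    differ when spot fluxes are unequal.  The averaged-image form is the
    default metric of the correction method.
    """
    if not spots:
        raise DegenerateInputError("metric requires at least one spot")
    shapes = {s.intensity.shape for s in spots}
    if len(shapes) != 1:
        raise ValueError("spot windows must share one size")
    if average_image:
        mean = np.mean([s.intensity for s in spots], axis=0)
        return MetricValue(
            value=central_second_moment(mean),
            n_spots=len(spots),
            total_flux=float(mean.sum()),
        )
    values = [central_second_moment(s.intensity) for s in spots]
    flux = float(np.mean([s.intensity.sum() for s in spots]))
    return MetricValue(value=float(np.mean(values)), n_spots=len(spots), total_flux=flux)
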