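"""Separability validation: cross-term metric scans, surface fits, parameter P.

For a mode pair (i, j) the metric is measured on a symmetric n x n grid of
coefficient pairs (49 measurements for the default n = 7) and fitted with a
rotated anisotropic paraboloid

    M(a_i, a_j) = A1*(a_i cos(t) - a_j sin(t))^2
                + A2*(a_j cos(t) + a_i sin(t))^2 + M0.

For a separable (diagonal) metric the rotation t vanishes; the scalar

    P = (max(|A1|, |A2|) / min(|A1|, |A2|) - 1) * sin(2 t)

is zero for a perfectly separable pair and diverges when the two modes are
proportional.  Comparing |P| statistics between a gradient-orthogonal basis
and a Zernike basis rendered on the same mirror quantifies how much the
orthogonalization buys.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import SurfaceFitError, UsageError
from .correction_loop import MicroscopeSystem
from .modal_basis import ModalBasis
from .pupil_optics import CameraImage

__all__ = [
    "CrossTermScan",
    "CrossTermFit",
    "crossterm_scan",
    "fit_crossterm",
    "parameter_P",
    "compare_bases",
    "add_detection_noise",
]


@dataclass(frozen=True)
class CrossTermScan:
    """Metric surface over a symmetric coefficient grid for one mode pair."""

    mode_i: int
    mode_j: int
    amplitudes_i: np.ndarray     # length-n uniform grid, symmetric about 0
    amplitudes_j: np.ndarray
    metric: np.ndarray           # (n, n), metric[k, l] at (a_i[k], a_j[l])
    n_evaluations: int


@dataclass(frozen=True)
class CrossTermFit:
    """Rotated-paraboloid fit of a cross-term surface."""

    A1: float
    A2: float
    theta: float                  # radians, in (-pi/4, pi/4]
    M0: float
    residual_rel: float           # residual norm / surface dynamic range
    reliable: bool                # residual_rel <= threshold

    @property
    def P(self) -> float:
        return parameter_P(self)


def crossterm_scan(
    system: MicroscopeSystem,
    basis: ModalBasis,
    i: int,
    j: int,
    amp_max_um: float,
    n: int = 7,
) -> CrossTermScan:
    """Measure the metric at every (a_i, a_j) on a symmetric n x n grid."""
    if i == j:
        raise UsageError("cross-term scan requires two distinct modes")
    if n % 2 == 0:
        raise UsageError("n must be odd so the grid includes 0")
    if system.basis is not basis:
        system.set_basis(basis, reset_correction=False)
    amps = np.linspace(-amp_max_um, amp_max_um, n)
    metric = np.empty((n, n))
    count0 = system.metric_evaluations
    for k, ai in enumerate(amps):
        for l, aj in enumerate(amps):
            extra = np.zeros(basis.n_modes)
            extra[i] = ai
            extra[j] = aj
            metric[k, l] = system.measure_metric(extra).value
    return CrossTermScan(
        mode_i=i,
        mode_j=j,
        amplitudes_i=amps,
        amplitudes_j=amps.copy(),
        metric=metric,
        n_evaluations=system.metric_evaluations - count0,
    )


def _surface_model(p: np.ndarray, ai: np.ndarray, aj: np.ndarray) -> np.ndarray:
    A1, A2, theta, M0 = p
    u = ai * np.cos(theta) - aj * np.sin(theta)
    v = aj * np.cos(theta) + ai * np.sin(theta)
    return A1 * u**2 + A2 * v**2 + M0


def _canonicalize(A1: float, A2: float, theta: float) -> tuple[float, float, float]:
    """Fold the axis-relabeling degeneracy into theta in (-pi/4, pi/4]."""
    theta = (theta + np.pi / 2.0) % np.pi - np.pi / 2.0   # (-pi/2, pi/2]
    if theta > np.pi / 4.0:
        theta -= np.pi / 2.0
        A1, A2 = A2, A1
    elif theta <= -np.pi / 4.0:
        theta += np.pi / 2.0
        A1, A2 = A2, A1
    return A1, A2, theta


def fit_crossterm(scan: CrossTermScan, unreliable_rel: float = 0.05) -> CrossTermFit:
    """Nonlinear least squares of the rotated paraboloid over the 49 points.

    Curvature starts come from the two axis-aligned 1-D parabolic fits; a
    small multi-start over theta avoids the local minimum at theta +/- pi/2
    with swapped curvatures.  Fits whose residual exceeds ``unreliable_rel``
    of the surface dynamic range are flagged unreliable.
    """
    if not np.all(np.isfinite(scan.metric)):
        raise SurfaceFitError("scan surface contains non-finite values")
    ai, aj = np.meshgrid(scan.amplitudes_i, scan.amplitudes_j, indexing="ij")
    ai = ai.ravel()
    aj = aj.ravel()
    m = scan.metric.ravel()
    mid = len(scan.amplitudes_i) // 2
    c_i = np.polyfit(scan.amplitudes_i, scan.metric[:, mid], 2)[0]
    c_j = np.polyfit(scan.amplitudes_j, scan.metric[mid, :], 2)[0]
    m0_init = float(scan.metric[mid, mid])
    best = None
    for theta0 in (-0.6, -0.3, 0.0, 0.3, 0.6):
        try:
            sol = least_squares(
                lambda p: _surface_model(p, ai, aj) - m,
                x0=np.array([c_i, c_j, theta0, m0_init]),
                method="lm",
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise SurfaceFitError("cross-term surface fit did not converge")
    A1, A2, theta, M0 = best.x
    A1, A2, theta = _canonicalize(A1, A2, theta)
    dynamic = float(m.max() - m.min()) or 1.0
    residual_rel = float(np.sqrt(2.0 * best.cost / m.size) / dynamic)
    return CrossTermFit(
        A1=float(A1),
        A2=float(A2),
        theta=float(theta),
        M0=float(M0),
        residual_rel=residual_rel,
        reliable=residual_rel <= unreliable_rel,
    )


def parameter_P(fit: CrossTermFit) -> float:
    """Separability parameter (max|A|/min|A| - 1) * sin(2*theta).

    Zero for a separable pair (theta = 0 or equal curvatures); infinite when
    the two modes are proportional (one curvature vanishes).
    """
    lo = min(abs(fit.A1), abs(fit.A2))
    hi = max(abs(fit.A1), abs(fit.A2))
    if lo == 0.0:
        return float("inf")
    return float((hi / lo - 1.0) * np.sin(2.0 * fit.theta))


def compare_bases(
    system: MicroscopeSystem,
    basis_orth: ModalBasis,
    basis_zern: ModalBasis,
    amp_max_um: float,
    subset_orth,
    subset_zern=None,
    pairs_orth=None,
    pairs_zern=None,
    n: int = 7,
):
    """Parameter-P matrices of two bases measured on the same simulated system.

    Scans and fits every pair from the given mode subsets (diagonal omitted:
    a mode against itself has infinite P by construction); explicit
    ``pairs_*`` lists override the all-pairs default, e.g. to scan a reduced
    representative pair set.  Returns ``(P_orth, P_zern, summary)`` where the
    P dicts map ``(i, j)`` to fits and the summary holds the median and max
    of |P| per basis over reliable pairs.  Fit failures are recorded per
    pair, not fatal.
    """
    if subset_zern is None:
        subset_zern = subset_orth
    results = {}
    for label, basis, subset, pair_list in (
        ("gradient_orthogonal", basis_orth, subset_orth, pairs_orth),
        ("zernike", basis_zern, subset_zern, pairs_zern),
    ):
        system.set_basis(basis)
        pairs = {}
        if pair_list is None:
            pair_list = list(itertools.combinations(subset, 2))
        for i, j in pair_list:
            try:
                scan = crossterm_scan(system, basis, i, j, amp_max_um, n=n)
                fit = fit_crossterm(scan)
                pairs[(i, j)] = {"fit": fit, "P": parameter_P(fit), "error": None}
            except Exception as exc:  # noqa: BLE001 - recorded per pair
                pairs[(i, j)] = {"fit": None, "P": float("nan"), "error": str(exc)}
        results[label] = pairs
    summary = {}
    for label, pairs in results.items():
        ps = [
            abs(rec["P"])
            for rec in pairs.values()
            if rec["fit"] is not None and np.isfinite(rec["P"])
        ]
        summary[label] = {
            "median_abs_P": float(np.median(ps)) if ps else float("nan"),
            "max_abs_P": float(np.max(ps)) if ps else float("nan"),
            "n_pairs": len(ps),
        }
    return results["gradient_orthogonal"], results["zernike"], summary


def add_detection_noise(
    image: CameraImage,
    photon_scale: float,
    read_noise: float,
    seed: int,
) -> CameraImage:
    """Poisson photon noise plus Gaussian read noise, deterministic per seed.

    ``photon_scale`` is the expected photon count at the brightest pixel;
    ``read_noise`` is the read-noise standard deviation in the same count
    units.  The returned image is rescaled to the input intensity units, so
    the noisy image converges to the clean one as ``photon_scale`` grows.
    """
    if photon_scale <= 0:
        raise UsageError("photon_scale must be positive")
    rng = np.random.default_rng(seed)
    clean = image.intensity
    peak = float(clean.max())
    if peak == 0.0:
        return CameraImage(clean.copy(), image.pixel_um, dict(image.meta))
    gain = photon_scale / peak
    counts = rng.poisson(clean * gain).astype(float)
    if read_noise > 0:
        counts += rng.normal(0.0, read_noise, size=counts.shape)
    noisy = np.clip(counts, 0.0, None) / gain
    meta = dict(image.meta)
    meta.update({"photon_scale": photon_scale, "read_noise": read_noise, "seed": seed})
    return CameraImage(noisy, image.pixel_um, meta)
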