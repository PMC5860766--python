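# Methods

`aosim` simulates sample-independent sensorless adaptive optics for
epifluorescence microscopy: a deformable mirror (or other adaptive optical
element, AOE) in the shared pupil plane is driven in a *gradient-orthogonal*
modal basis, and arbitrary pupil aberrations are corrected from 2N+1
measurements of a second-moment sharpness metric taken on images of
point-like excitation spots.  This note records the model, its assumptions,
the parameters that matter, and the numerical choices.

## Physical model

The microscope is a unit-magnification telescope.  A pupil field
`E_p = P(x, y) exp(i φ(x, y))` — binary disk aperture `P`, phase aberration
`φ` in radians — is propagated coherently to an axial stack of object planes:
`E_o(·, z′)` is the centered unitary DFT of `P exp(i(φ + φ_z′))`, where
`φ_z′ = π (x² + y²) z′ / (λ f²)` is the quadratic defocus phase of plane z′
(the pure axial phase prefactor of the Fresnel propagator is dropped; it
never affects intensities).  Fluorescence emission at each plane is the
excitation intensity times the fluorophore concentration `O(x′, y′, z′)`;
because emission is incoherent, the camera image is the per-plane 2-D
convolution of the emission with the coordinate-mirrored detection PSF of the
mirror plane −z′ (same aberration, opposite propagation direction), summed
over planes with uniform weights (equal excitation power per plane — energy
per plane is conserved exactly by the unitary transform).  Convolutions are
evaluated in the Fourier domain and are circular; image formation is exactly
linear in `O`, and piston phase is exactly irrelevant.

Assumptions inherited from this model: scalar (low-NA) diffraction, no
apodization or polarization; isoplanatic aberrations (one pupil phase for the
whole field); identical excitation and emission wavelengths (no Stokes
shift); magnification 1; no photon or read noise in the core model (noise is
available as a validation fixture, `add_detection_noise`).

## Metric

For an image `I`, the metric is the central second moment
`sm(I) = Σ I·((r−r̄)² + (c−c̄)²) / Σ I` in pixel², taken on the pixel-wise
average of background-subtracted crops around the brightest spots
(`extract_spots` → `metric_from_spots`).  Central moments make the metric
blind to image translation, so tip and tilt (and, through the plane sum,
defocus) displace rather than degrade it.

Two readings of "averaged over multiple positions" exist — second moment of
the averaged spot image, or mean of per-spot second moments.  They coincide
for equal-flux spots and differ otherwise; the averaged-image form is the
default and the other is an option (`average_image=False`).

In the continuous model with an unbounded detector, the metric is *exactly*

```
sm(φ) = sm(0) + k · Σ_i b_i²
```

for any displacement-free aberration `φ = Σ b_i g_i` expressed in a
gradient-orthogonal basis — a diagonal quadratic at any amplitude, which is
what makes the 2N+1 protocol exact.  Two numerical effects perturb this in
simulation:

* **Detection-area truncation.**  Cropping the image to a finite window
  couples the modes at the percent level (measured Hessian cross terms ≈ 2%
  for a 128-px window on a 256² frame).  This is the method's own physical
  limit — a detector too small for the spread light — so accuracy studies
  compute the metric on the full camera frame (`MicroscopeSystem(window=None)`,
  single centered spot), while windowed multi-spot extraction remains the
  realistic detector model.  With the full frame the residual mode coupling
  is set by grid discretization alone (≈0.1–1%, halving per grid doubling).
* **Periodic wrap.**  The DFT grid is periodic; far diffraction tails wrap.
  The axial range is capped so the geometric out-of-focus blur diameter stays
  within a quarter of the analysis window (`usable_axial_range`), which keeps
  wrapped/truncated flux negligible.

## Axial range and sampling

The plane sum should span the range `±T` beyond which defocused light
carries no sharp detail: `estimate_T(factor)` returns the smallest z′ where
the unaberrated defocused second moment exceeds `factor` (default 10) times
the in-focus value.  On a finite grid that range can exceed the validity
bound above, so the default half-range is the *minimum* of the two
(`usable_axial_range`); at the reference configuration the window bound is
the binding one (±4.2 µm).  Nine planes sample the range: the metric's
mode dependence is plane-independent in theory (each plane contributes the
same `Σ b_i²` term plus a defocus-dependent constant — the defocus component
of `φ_z′` is gradient-orthogonal to displacement-free aberrations), and the
simulations confirm plane-count insensitivity, so a dense 33-plane stack
buys nothing at 3–4× the cost.

## Gradient-orthogonal basis

The gradient dot product `φ₁ ∴ φ₂ = ∫_P ∇φ₁·∇φ₂ dx dy` is evaluated by
central differences on normalized pupil coordinates (aperture edge at
ρ = 1), integrated over the full mask.  Phase maps generated by the package
(Zernike polynomials, Gaussian influence functions, defocus) extend smoothly
past the mask edge, so boundary differences are valid; excluding a one-pixel
boundary ring is available (`exclude_boundary=True`) for maps defined only on
the mask, but it under-integrates the disk by ≈2/R_px and is off by default
(tip ∴ tip must equal 4π, and does to 0.25% at R = 32 px).

From the influence functions `φ_i` of the mirror's actuators the matrix
`G_ij = φ_i ∴ φ_j` is built either by direct quadrature or from simulated
Shack-Hartmann slopes.  `G` is symmetric positive semi-definite, so its SVD
coincides with its eigendecomposition: eigenvectors (sorted by decreasing
singular value, first nonzero component positive for determinism across
linear-algebra backends) give actuator commands whose realized phases are
pairwise gradient-orthogonal.  Modes below `sv_cutoff_rel` (default 10⁻³) of
the largest singular value are dropped.  Retained modes are rescaled to unit
gradient norm (`∫|∇g|² = 1`); the published figures show a normalized basis
but do not state the convention, so this one — which makes all metric
curvatures equal — is documented here and tested.

The three modes most similar to tip, tilt and defocus are flagged and
excluded from correction so that correcting never displaces or refocuses the
field of view.  "Most similar" is measured by normalized gradient-space
correlation `|g ∴ Z_k| / √((g ∴ g)(Z_k ∴ Z_k))` against Noll Z2, Z3, Z4; each
Zernike must claim a distinct mode, otherwise the ambiguity is an error that
reports the correlation table.

### Simulated mirrors

`synth_influence_functions` emulates a deformable mirror as Gaussian phase
bumps on a square or hexagonal actuator lattice slightly larger than the
pupil (lattice radius 1.08).  The bump width is set by the nearest-neighbor
coupling (bump value at the neighboring actuator center; default 0.3, a
typical mid-coupling mirror).  A small seeded jitter (1.5% of pitch on
positions, 2% on gains) breaks the lattice symmetry, as real mirrors do; this
also removes eigenvalue degeneracies, keeping the SVD mode ordering stable.
The reference low-order mirror is a 43-actuator hexagonal device calibrated
to 35 retained modes — 32 correction modes plus the displacement trio, the
retained-mode count of a comparable commercial low-order mirror; the
discarded smallest-singular-value modes are also the most finely structured,
i.e. the ones most affected by grid discretization.  A 69-actuator hexagonal
device serves as the high-order example.

## Shack-Hartmann model

The sensor is an ideal calibrated slope sensor: per lenslet, the mean
central-difference gradient of the phase over the subaperture's pupil pixels
(no lenslet diffraction, no noise — the calibration treats centroid
displacement as mean slope).  The gradient-product estimator is the
covered-area-weighted mean of `dx·dx′ + dy·dy′` over subapertures, rescaled
by the pupil area; a constant slope `s` then yields exactly `s²·(pupil
area)`, the direct-quadrature value.  Any subaperture overlapping the pupil
participates (weighted by its covered area): the gradient energy of pupil
aberrations concentrates at the aperture edge, and discarding half-covered
edge lenslets biases the estimator low by ≈2%.  A coverage threshold
(`min_coverage`) is available to emulate a real sensor's validity rule.  At
30×30 lenslets (~750 valid subapertures) the estimator matches direct
quadrature within ~1% for smooth random aberrations; agreement on the full
`G` of a Gaussian-bump mirror needs a denser array because the bump
curvature within one lenslet is larger.

## Correction protocol

Per iteration: measure `M0` once; for each of the N correction modes measure
`M±` with the mode probed at ± the probe amplitude on top of the current
correction; the vertex `a(M₋ − M₊) / (2(M₊ + M₋ − 2M₀))` of the parabola
through the three points is the mode's optimal increment.  All increments
are computed from the same frozen state and applied together at the end of
the iteration — exactly 2N+1 metric measurements, which the counter asserts.
The second moment is *minimized*, so only fits with positive curvature are
accepted; non-convex fits are skipped and logged, and an optional clamp
(`clamp_factor`) bounds each increment against wild extrapolation from noisy
data.  The probe amplitude defaults to 0.3 µm of wavefront per
unit-gradient-norm mode: large enough for a well-conditioned three-point fit,
small enough that the probed state stays within the simulator's validity.

Whether a physical implementation applies corrections per mode or jointly is
not dictated by the 3-point algebra, but the 2N+1 budget implies no
re-measurement between modes; the joint reading is implemented.

## Separability validation

For a mode pair (i, j), the metric is scanned on a symmetric 7×7 coefficient
grid (49 measurements) and fitted with the rotated paraboloid
`A1(a_i cosθ − a_j sinθ)² + A2(a_j cosθ + a_i sinθ)² + M0` by
Levenberg-Marquardt, curvatures initialized from the two axis-aligned 1-D
parabolic fits and θ multi-started over five angles (the model has an exact
θ ± π/2 relabeling degeneracy, folded afterwards into θ ∈ (−π/4, π/4] by
swapping curvatures).  The separability parameter

```
P = (max(|A1|, |A2|) / min(|A1|, |A2|) − 1) · sin(2θ)
```

is zero for a separable pair and diverges when the modes are proportional.
Two caveats: for A1 ≈ A2 the surface is rotationally degenerate and θ (hence
P's sign) is ill-conditioned while P itself stays near zero — this is why
summaries use |P| and why θ is not itself a pass/fail quantity for the
normalized orthogonal basis, whose curvatures are all equal by construction.
Fits whose residual exceeds 5% of the surface dynamic range are flagged
unreliable rather than silently reported.

The basis comparison scans both a gradient-orthogonal basis and a Zernike
basis *rendered on the same mirror* (least-squares actuator fits — using the
mirror is what makes the comparison fair, and is how a Zernike basis is used
in practice when no calibration is available).  The Zernike side uses a
reduced representative pair set: the azimuthally matched cross-order couples
up to 8th order (Z5–Z13, Z6–Z12, Z11–Z22, Z7–Z17, Z8–Z16 — the canonically
non-gradient-orthogonal pairs, |P| ≈ 1–1.5 in simulation) plus neighboring
uncoupled controls; the orthogonal side scans all pairs of its leading
correction modes (|P| at the 10⁻³ fit-noise floor).  This mirrors the
published contrast: every Zernike element has at least one strongly coupled
partner, the optimal basis has none.

## Reference study conditions

Fixed in `aosim.studies` and used by the validation tests and
`scripts/acceptance.py`: λ = 0.52 µm, f = 5 mm, D = 5 mm (paraxial NA 0.25);
256² grid at pupil fill 0.5 for imaging accuracy studies (image pixel
0.26 µm), 128² for budget/scan studies; full-frame metric, single centered
spot for accuracy, 3×3 spot array with 64-px windows for the budget study;
9 axial planes over ±`usable_axial_range`; the 43-actuator hexagonal mirror
with 32 correction modes; probe 0.3 µm; mild test aberrations draw every
mode coefficient uniformly within 0.75× probe (one iteration expected to
correct), severe within 2× probe (two iterations).  On these conditions the
simulations give: single-mode coefficient recovery to ≪1%; gradient-norm
reduction in one iteration of typically 97–99% for mild aberrations (the
worst trial depends on the seeded mirror realization — most realizations
stay above 95%, occasional ones dip to ~94% through their worst-coupled mode
pair) and ≥99% after two iterations for severe; slope-estimator agreement
within 2% at ~750 subapertures; basis-Gram off-diagonals below 10⁻³; and the
basis-comparison median |P| contrast of roughly three orders of magnitude.

## Synthetic data vs real data

The generators emulate: smooth low-order pupil aberrations (random Zernike
combinations), mirror influence functions (Gaussian bumps), an ideal slope
sensor, and point-like excitation spots over a uniform fluorophore
distribution (with a uniform object, shifting the excitation spot shifts the
image rigidly, so multiple spots are simulated by rolling one rendered
frame).  They do not emulate: lenslet diffraction or centroiding noise,
mirror hysteresis/saturation, depth-varying (anisoplanatic) aberrations,
non-uniform or sparse fluorophore distributions, Stokes shift or dispersion,
or photon-limited detection (available only as an explicit noise fixture).
Passing tests therefore demonstrate the correctness of the *method and its
implementation* under the model's assumptions, not the performance of any
physical instrument.

## Known limitations

* Scalar paraxial optics; results at high NA are qualitative only.
* The full-frame metric option requires a single centered spot; windowed
  multi-spot metrics inherit a percent-level mode coupling from truncation.
* Discretization couples the finest modes (worst ≈1.4% Hessian cross-talk at
  256²); corrections involving many fine modes converge in more iterations
  than the continuous theory predicts.
* `estimate_T` scans the unaberrated system; strong aberrations change the
  axial intensity profile and would shift the physically ideal range.
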