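# Methods

## Model

A spherical particle of diameter D cut by (or adjacent to) a section
of thickness T presents a circular profile. Interiors (centre inside
the slab) show d = D; caps centred a distance dz < D/2 outside a
surface show d = √(D² − 4 dz²), from (½D)² = (½d)² + dz². The cap
angle θ = asin(d/D) measures, independently of particle size, how deep
the section cut into the particle. The lost-cap model assumes a single
limit φ: caps with θ < φ are unobserved. With F(d) the 3D diameter
density and μ_D its mean, the observed projected-diameter density is

    G(d) = (T/ζ) F(d) + (d/ζ) ∫_d^{u(d)} F(y)/√(y² − d²) dy,
    ζ = T + μ_D cos φ,

where the upper limit u(d) = d/sin φ (a sphere of diameter y shows a
cap of apparent diameter d only if d ≥ y sin φ), read as ∞ at φ = 0
and as an empty interval at φ = 90°. The printed forms of this
integral are typographically ambiguous in parts of the literature; the
limits used here are forced by the cap geometry and by the required
reductions: φ = 0 gives the classical thick-section (Bach) solution,
φ = 0 and T = 0 the Wicksell planar solution, and φ = 90° gives
G = F. Integrating G over d confirms normalisation analytically:
∫ cap term = μ_D cos φ / ζ, so ∫G = (T + μ_D cos φ)/ζ = 1.

ζ is the mean axial extent containing the centres of observed
particles, which yields the density correction λ₃D = λ₂D/ζ. Setting
φ = 0 recovers the Abercrombie correction; substituting
θ_min = asin(d_min/μ_D) for φ gives the minimum-observed-diameter
correction. The volume fraction follows either as
VF = λ₃D·E[(π/6)D³] or from the observed area fraction as VF = K_v·AF
with the Weibel–Paumgartner factor

    K_v = 2 m₃ / (2 m₃ + 3 g m₂ − 3X² + X³),
    m₂ = 1 + CV², m₃ = 1 + 3 CV², g = T/μ_D, X = 1 − cos φ,

the last term expressing the lost-cap truncation through φ.

### Assumptions

Spherical particles, spatially random (hard-core packing does not
affect any marginal quantity used here), a size-independent φ, and
sections cut independently of the particle process. A per-particle
Gaussian φ (supported by direct z-stack measurements) violates the
fixed-φ assumption mildly; the simulator implements it, and fixed-φ
fits on Gaussian-φ data carry sub-degree bias for mean φ below ~45°
(verified by test).

## Numerics

* **Cap integral.** The substitution u² = y² − d² removes the
  inverse-square-root singularity at y = d; the substituted integrand
  is smooth and is integrated by fixed-order Gauss–Legendre (120
  nodes), vectorised over the whole d-grid — this is what the fitter
  evaluates. A scalar adaptive-quadrature path (relative tolerance
  1e-8, our choice) offers both the substitution and a legacy variant
  that floors the raw denominator at 1e-7; the two agree to better
  than 1e-4 (tested).
* **Support truncation.** Gaussian F is truncated to
  [max(0, μ−6σ), μ+6σ]; at the size spreads targeted (CV_D ≤ ~0.2) the
  clipped mass is < 1e-8. The integral's upper limit is capped at the
  support maximum.
* **Angles** are degrees at every API surface, radians internally.
* **Lengths** are unit-agnostic; simulation defaults use unit
  diameters (u.d.), μ_D = 1.

## Estimation

Histograms are normalised counts/(n·h) on uniform bins anchored at
multiples of the bin width. The fit minimises unweighted squared
residuals between bin densities and the forward curve at bin centres
with Levenberg–Marquardt (scipy `least_squares`, method="lm");
a Poisson-weighting option exists but is off by default. No box
constraints are applied; a φ that converges outside [0°, 90°] is
folded back (|φ|, mirrored at 90°) for reporting and flagged. Initial
guesses are the binned moments and φ₀ = asin(d_min/μ_d); apparent
non-convergence triggers restarts with φ₀ jittered ±10° (3 attempts).
Parameter uncertainties are 1-sd values from the local curvature
(JᵀJ)⁻¹ scaled by the residual variance. The simultaneous fit shares
(μ_D, σ_D) across histograms with one φ each, stacking residual
vectors with equal weight (whether the original analyses weighted by
sample size is unstated; equal weighting is this package's choice).

### Cap-angle cutoff and accuracy test

φ is estimable from G(d) only while enough cap tail is visible. The
calibrated bounds are

    sin φ_cutoff ≈ 1.043 − 1.534·CV_D − 0.517/√n − 17.106·CV_D/√n

with true moments, and

    sin φ_cutoff ≈ 0.987 − 2.071·CV_D + 0.124/√n − 35.059·CV_D/√n

with fitted moments; nominal calibration range CV_D 0.04–0.17,
n 200–2000 (outside it the functions warn but compute). For
histograms whose diameters come from tracking particles through a
z-stack, n is reduced 3-fold (tracked outlines of one particle are not
independent draws). The φ-accuracy verdict passes iff fitted
φ < estimated cutoff **and** the φ fit uncertainty is ≤ 5° — the
published workflow pairs the cutoff with "small fit errors (1–2°)"
against ">80°" failures without naming one number; 5° is this
package's default, configurable.

## Simulator

Hard spheres with diameters drawn from F are packed into a periodic
cuboid at a target volume fraction (default 0.40, the study
condition). The xy square is sized from the expected λ₂D so one
projection holds ~500 observed particles (default); the z extent holds
the configured number of section slots. Packing: random insertion at
reduced diameter scale, then gradual inflation to full size with
deterministic pairwise push-apart relaxation after each step
(Jodrey–Tory style). This replaces a Metropolis random-displacement
relaxation as the package's own choice: it converges far faster at
VF 0.40 (above the ~0.38 random-sequential-addition jamming limit) and
is fully seeded. Realized VF matches the target to < 1% by
construction; the hard-core property is asserted in tests. A
"poisson" arrangement skips the hard-core constraint for studies that
only need the marginal axial geometry (e.g. G(d) sampling), and a
direct sampler (`sample_projected_diameters`) draws observed projected
diameters without any packing — the marginal law is identical, which
tests verify by KS comparison.

Per-projection rules follow the measured-image phenomenology:

* **Lost caps** — observed iff θ ≥ φ, with φ fixed or drawn per
  particle from a Gaussian (μ_φ, CV_φ).
* **Semi-transparency** — Ω sums each particle's fractional circle
  overlaps with particles higher in the section (closer to the
  imaging surface, the z-max face; ties broken by id), normalised by
  the particle's own projected area so Ω > 1 reads "likely completely
  hidden". Particles with Ω > ψ are removed (ψ = 0.25 in the overlap
  studies).
* **Opacity** — pairs whose Hilliard parameter
  α = (4d₁₂² − d₁² − d₂²)/(2 d₁ d₂) lies in (−1, 0) merge into one
  composite with the union area, iterating from the particle nearest
  the surface; α ≤ −1 (full containment, α = −1 exactly for
  concentric equal circles) hides the deeper projection without
  growing the composite. The dimensionless form of α is used: the
  alternative printed form (½d₁·d₂)(4d₁₂²−d₁²−d₂²) is dimensionally
  inconsistent with the −1 < α < 0 criterion. The rule reproduces the
  expected positive skew of opaque-particle G(d) (tested).

The disector simulation tiles reference/lookup pairs of thickness
0.3 u.d. and counts particles observed in the reference (cap-angle
limit φ_lookup + φ_bias, emulating a blind first detection) but not in
the lookup (φ_lookup); λ₃D = count/(area·T). With φ_bias = 0 the
counted axial measure is exactly T for every diameter, so lost caps
cause no bias; a positive φ_bias shrinks it by
(D/2)(cos(φ_lookup+φ_bias) − cos φ_lookup), the undercount the tests
quantify (≈ −21% at φ_lookup = 42°, φ_bias = 10°).

Error statistics report percent differences for sizes and densities
and plain differences for angles; when |skew| > 0.5 the bias is the
median and the spread is split above/below it.

## z-stack analysis

Profiles (z-index, radius) fit the axially stretched circle
r = √((D/2)² − (z/E)²), z = z#·S_z − z0, with S_z fixed. r² is an
exact quadratic in z, giving closed-form start values, refined by
damped least squares on the radius residuals. Fits require ≥ 3 planes
spanning both sides of the maximum. Because the fitted eccentricity
scales linearly with the assumed S_z, axial shrinkage is estimated by
root-solving mean fit E = 1 (isotropic-orientation assumption; a
systematically elongated sample folds its elongation into S_z, which a
dedicated test documents). Per-pole cap-angle limits are
φ = asin(δ_min/D) with δ_min the outline diameter at the extreme
measured plane on each side of the centre; poles not strictly inside
the stack's z range are skipped, and caps whose last outline touches
the stack boundary are excluded rather than truncated. Plane
discretisation biases measured φ upward (≈ +1° at S_z = 0.012 u.d.,
φ = 40°, reproduced by test; much larger at coarse spacing and small
φ).

Tomography resolution: ρ_x = T_tissue·π/N_tilt (Crowther, 180° scan)
and ρ_x = T_tissue·Δ_tilt with Δ_tilt the tilt increment in radians;
the missing wedge elongates axially by
e_xz = √((α + sin α cos α)/(α − sin α cos α)) — the ratio reading is
forced by e_xz(65°) = 1.4 and the limit e_xz → 1 at α = 90° —
giving ρ_z = ρ_x·e_xz.

## Synthetic data and what the tests show

The generators emulate the study conditions: Gaussian F(d) with
CV_D 0.04–0.17 (default 0.09), ~200–2000 diameters per sample, fixed
or Gaussian φ (CV_φ 0.2), T from 0 to ~1.3 mean diameters, VF 0.40,
and an ET-like z-stack at 42.9 ± 3.4 nm, φ = 41.5°, S_z = 0.53 nm.
They include sampling stochasticity, lost caps, overlap/opacity
censoring and axial discretisation, but not irregular particle shape,
finite lateral resolution, outlining error beyond additive radius
noise, or spatial clustering. Passing tests therefore demonstrate the
estimators' correctness and calibration under the model's own
assumptions — not robustness to non-spherical or clustered real
specimens, which must be judged per dataset (the φ-accuracy test and
the E ≈ 1 isotropy check are the built-in guards).

Problem sizes used by the test suite are desk-scale choices:
parameter-recovery studies run 40 repetitions of ~500 diameters,
disector studies 12–14 section pairs of ~120–150 particles each,
model-vs-simulator equivalence 10⁵ sampled diameters per condition,
and packings up to a few thousand spheres. Biases resolved at these
sizes are quoted with tolerances widened to ~2 per-rep standard
deviations.

## Known limitations

* Fitting assumes a unimodal parametric F(d); multimodal mixtures are
  out of scope (the forward model extends naturally).
* No nonparametric unfolding of G(d); the model is fit, not inverted.
* Uncertainties are curvature-based, not bootstrap.
* The gamma family needs f ≳ 170 (not 70) to sit within KS 0.01 of a
  matched Gaussian; its skew decays as 2/√f.
* At T = 0 and φ ≥ 55°, G is a scale-shifted F (KS ≈ 0.2 at 55°):
  "G ≈ F" in that regime is an observation at histogram resolution,
  not a distributional identity.
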