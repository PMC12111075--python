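# Methods

This note records the models, parameter choices and numerical decisions
behind `geldose`, in the order the pipeline runs them.

## Phantom and study conditions

The phantom is a voxelized hemiellipsoid shell standing on the plane
z = 0: gel between an outer boundary with semi-axes (66, 66, 55) mm and
an inner dome (48, 48, 45) mm, 2.5 mm glass walls outside/inside those
surfaces plus a base slab, and water filling the dome (the prosthesis
space).  The published experiment states the gel fill volume (0.282 L),
the port dimensions and the acquisition geometry but not the vessel's
outer dimensions, so the silhouette is a plausible reconstruction; the
semi-axes were chosen once so the closed-form shell volume (0.2846 L)
and its voxelization land within ~1% of the stated fill.  The metal
port — a disk 17.9 mm across and 3.9 mm thick — is attached from the
water side to the inner-dome surface at y = +24 mm, so a mirror-image
port-free slice exists at y = −24 mm.  The default grid is the
acquisition resolution: 140/144 ≈ 0.97 mm in-plane (x, z), 2 mm slices
along y, 144 × 72 × 68 voxels.

Beam axis is x (opposed lateral beams at gantry 90°/270°), slice axis is
y, vertical is z.  The planned dose is an analytic surrogate for the
treatment planning system: per beam,

    D(x) = (Rx/2) · (1 − e^{−d/b}) · e^{−μ_eff·d} · w(z) · A(y, z)

with depth d along the beam through phantom material, buildup length
b = 4 mm (placing the depth-dose peak near 16 mm, standard for 6 MV),
effective attenuation μ_eff = 0.046 cm⁻¹, a linear 15° wedge gradient
w(z) = 1 + tan(15°)(z_iso − z)/100 mm, and the 19 × 20 cm² aperture; the
two-beam sum is renormalized to 3 Gy at the isocenter.  Setting the
buildup length to zero recovers a pure exponential depth dose.  The
buildup term matters structurally: without it the hottest voxels sit on
the entrance surface inside the near-wall deficit band, which would
couple the normalization to the wall artifact.

The delivered (ground-truth measured) dose perturbs the plan on gel
voxels only:

* **Near-wall inhibition.**  Oxygen diffusing from the glass quenches
  polymerization.  The deficit is `f_w · exp(−max(0, d − p)/r)` with
  full fraction f_w = 0.045 within a plateau p = 4 mm of any wall,
  decaying with range r = 1 mm beyond it — a saturated inhibition layer
  with a sharp front, consistent with the few-mm edge artifacts reported
  for normoxic gels.  The deficit fraction derives from the published
  port-free profile deficits (4.71% and 4.21%).
* **Port shadow.**  A voxel is shadowed when its ray along the beam axis
  intersects the metal disk (parallel-beam projection; the port is small
  relative to the source distance, so divergence is negligible).  Inside
  the shadow the *total* deficit deepens to f_s = 0.098 (the published
  with-metal value): the extra factor is (f_s − f_w)/(1 − f_w), so that
  wall and shadow terms compose to exactly f_s where the wall term is
  saturated.  The shadow indicator is edge-blurred by a 0.5 mm Gaussian.

The MR signal model is S(TE) = S₀·exp(−R2·TE) with R2 = R2₀ + α·D,
defaults R2₀ = 3 s⁻¹ and α = 3 s⁻¹Gy⁻¹ (typical for MAGIC-f at 3 T;
with a 3 Gy prescription the working range stays linear).  Noise is
Rician: two independent Gaussian channels of width σ added before the
magnitude.  The default σ = 8.004 (S₀ = 1000) is the closed-form
solution of `noise_sigma_for_uncertainty`, the value at which the mean
calibration dose uncertainty equals the stated 3.0%.  The scanner bias
field is a sum of four random Gaussian blobs normalized to unit mean
over the phantom; it multiplies S₀ by default, or R2 in the
`r2_mult` mode that the end-to-end pipeline uses so that the
reference-based correction has real work to do.

## Relaxometry and correction

The default fit is weighted least squares on log S with weights S²
(delta-method variance; near-ML at high SNR), a nonlinear exponential
fit being retained for validation.  Voxels with fewer than three
positive echoes, or a first echo below `snr_floor`·σ, are masked rather
than fitted.  The fit standard error comes from the known channel σ
when available, otherwise from weighted residuals.

Magnitude MR noise has a Rician floor that biases late, low-signal
echoes upward and hence R2 (and the recovered dose) downward, by an
amount that grows with R2.  Because the bias is dose-dependent it does
not cancel in relative distributions, so the pipeline enables the
noise-floor subtraction S ← √max(S² − 2σ̂², 0) using the background
sigma estimated from the Rayleigh relation (mean background magnitude =
σ√(π/2)).  A ~1% residual slope effect at the highest vial doses
remains and is visible only at sample sizes far beyond a vial ROI.

The inhomogeneity correction is multiplicative on R2: the reference
phantom's fitted R2 map is Gaussian-smoothed (20 mm default) inside its
mask, normalized to unit mean, and divided out.  This contract is fixed
by round-trip testability: a multiplicative R2 bias shared by
measurement and reference is removed to < 0.5% RMS.  Whether the
original analysis divided R2 maps or signal images is not stated; the
multiplicative-R2 rule is this package's definition.  An amplitude
(S₀) bias leaves fitted R2 untouched, in which case the correction is a
no-op by construction.

## Calibration diagnostics

Vial ROIs are eroded 2 mm from the glass before voxelwise fitting.  The
line is fitted by inverse-variance WLS with the variance of a vial mean
taken as R2_sd²/n (known), so parameter standard errors come from
(XᵀWX)⁻¹ rather than a 9-point residual estimate.  Pearson r is
computed on the nine (dose, mean-R2) pairs.  Mean uncertainty is the
average of 100·(R2_sd/α)/D over positive-dose vials.  Dose resolution
uses D_Δp = k_p·√2·σ_D with the two-sided Gaussian coverage factor
k_95% = 1.96 by default; the factor is exposed because other conventions
(e.g. 2.77) appear in the literature.  The published 3.0% uncertainty
and the printed 0.07/0.02 Gy resolutions cannot both be reproduced under
one coverage factor without the raw vial spreads, so only the formulas
are contracted, not those two printed values.

## Normalization and registration

Both distributions are expressed in % of their own robust maximum: the
99.5th percentile of valid voxels (configurable to 100 for the literal
single-voxel rule), read from a 3 mm masked-smoothed copy so that voxel
noise cannot inflate the percentile of the measured volume relative to
the noiseless plan.  The normalization voxels are restricted to gel
farther than 8 mm from any wall — the known-artifact band must not set
the scale.  Normalizing the calibrated dose map rather than the R2 map
is a deliberate choice; with a nonzero calibration intercept the two
differ, and the dose-map convention is the one with a physical scale.

In synthetic mode the phantom is simulated directly in the planned
frame with coincident fiducials: the registration stage still runs
(closed-form Procrustes with proper-rotation enforcement) and recovers
the identity, and the transform machinery is exercised separately by
synthesize-and-recover tests.  Measured volumes are pulled onto the
planned grid by trilinear interpolation; target voxels that map outside
the source, or touch masked voxels, become invalid rather than zero.

## Gamma analysis

Global 3D gamma at 3%/3 mm with a 10% low-dose threshold, evaluated at
planned-grid voxels searching the measured distribution (the swap is a
matter of argument order).  Candidate offsets lie on a subvoxel lattice
(spacing/interp_factor per axis) within a search radius of 3·DTA,
processed in order of increasing radius with per-voxel termination once
the distance term alone exceeds the current best — exact for this
discretization, as the exhaustive oracle in the test suite confirms to
10⁻¹⁶.  Where the search truncates, gamma is capped at radius/DTA.
Passing is γ ≤ 1 with a 10⁻⁹ epsilon so that exact boundary cases (a
uniform +3% offset) pass.  The dose-difference scale uses the global
normalization of the reference distribution; the end-to-end pipeline
passes relative volumes and pins it to 100%.  The threshold in the
Methods of the source experiment is 10% (its abstract says 15%; the
default follows the Methods and both are selectable).  The pipeline
evaluates gel voxels only and reports, besides the overall rate, a
wall-excluded rate on gel eroded 3 mm from the walls — the wall band is
a known gel artifact, excluded qualitatively in the original analysis.

## Profile statistics

Profiles are trilinear line samples (2/mm).  The deficit region of each
line is where it crosses the port's geometric shadow, inset ~1 voxel
from walls and shadow edges so trilinear validity margins and edge blur
do not dilute the statistic: for the horizontal (beam-axis) line at the
port-centre height, the near-dome segments 1.5–4.5 mm outside the dome
wall on both sides; for the vertical line (5 mm outside the dome-wall
radius), ±1.2 mm about the port-centre height.  The port-free slice at
−y uses the mirror-identical geometry.  Each orientation averages a
bundle of three parallel lines 2 mm apart within the shadow band — the
published analysis drew single dotted lines whose exact endpoints are
figure-defined; the bundle is this package's noise-robustness choice and
does not change what is measured.  The metal-attributed reduction is
the mean of the pairwise (with − without) deficit differences over the
two orientations; its uncertainty is propagated as the root-sum-square
of the paired spreads divided by the number of pairs (a documented
convention, not a published one).

## What the simulator does and does not emulate

Emulated: mono-exponential multi-echo decay, Rician magnitude noise at
a level calibrated to the stated 3% dose uncertainty, a smooth
multiplicative scanner bias recoverable from a reference scan, a
two-beam wedged planned dose with buildup and attenuation, near-wall
polymerization inhibition, and the port's beam shadow with the
published deficit magnitudes.  Not emulated: CT imaging and metal
artifacts, TPS beam modelling (collapsed-cone etc.), scatter and beam
divergence, gel chemistry kinetics and temporal drift, B1/slice-profile
effects, susceptibility distortions near the metal, and deformable
positioning errors.  Passing tests therefore demonstrate that the
analysis chain recovers known perturbations of the stated size and
structure through realistic noise — not that it would be robust to
every systematic effect of a physical scan.

## Problem sizes and runtime

Defaults were chosen so a full run is interactive on one CPU: the
144 × 72 × 68 acquisition-resolution grid (~150k gel voxels) runs the
complete chain in a few seconds, the gamma stage (subvoxel factor 2 in
the pipeline configuration; finer factors are available) in a further
few seconds.  The acceptance script averages the profile statistics
over 20 derived seeds (the gamma stage is run on the first seed only,
since its output does not enter those statistics) and uses 100
500-voxel vial batches for the calibration-quality replicate; it
completes in about a minute.

## Known limitations

* The log-linear fit degrades when late echoes approach the noise
  floor (first-echo SNR below ~10 at R2 ≳ 15 s⁻¹); the floor
  subtraction removes most, not all, of the resulting dose bias.
* The wall-deficit plateau/range and the shadow edge blur are model
  choices constrained only by the published region statistics, not by
  measured profiles of the inhibition layer.
* Rigid registration only; the glass phantom justifies it, soft-tissue
  applications would not.
* The gamma search samples the evaluated distribution on a finite
  lattice; γ is exact for that lattice, and slightly conservative
  relative to the continuum optimum for coarse interpolation factors.
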