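# Methods

This note documents the models, conventions and design choices behind
`radstab`: what is computed, what the synthetic data emulate, and what
passing tests do and do not demonstrate about real CT data.

## Feature definitions and conventions

All features are computed in 3D over the voxel set Ω of a contour applied to
a volume of HU values.

**Histogram family.** Moments use the population convention (divide by
|Ω|): mean, standard deviation σ, variance σ², skewness (third central
moment / σ³) and kurtosis. Kurtosis defaults to the standard σ⁴
normalisation; a `kurtosis_denominator="sigma3"` option reproduces an
alternative printed convention that divides the fourth central moment by σ³
(dimensionally inconsistent, kept for comparability). The median of an
even-sized sample is the lower-middle order statistic (deterministic and
integer-preserving). Entropy (base-2) and energy are computed from a
normalised histogram with one bin per integer HU — CT values are integer
calibrated, so this avoids an arbitrary bin-width choice; synthetic float
volumes are rounded to integer HU for these two features only. For a
constant ROI (σ = 0), skewness and kurtosis are reported as 0.

**GLCM family.** The co-occurrence matrix at offset d counts ordered voxel
pairs (x, x+d) with both ends in Ω, on labels quantized into `levels`
equal-width bins spanning the ROI's [min, max] (the maximum maps to the top
level; a constant ROI maps to level 1). Matrices are symmetrized (transpose
added before normalisation) by default, which makes the 26-neighbourhood /
13-offset reduction exact and forces Pₓ = P_y, μₓ = μ_y. Levels are indexed
1…L in all formulas, so a constant ROI has sum average exactly 2. GLCM
entropy, sum/difference entropies and the information-measure entropies use
the natural log; 0·log 0 := 0 throughout.

Two features follow printed-form conventions with classical variants behind
flags: information correlation B is `1 − exp(−2 (Hxy2 − Hxy))` (`icb_sqrt`
adds the square root) and the maximal correlation coefficient is the
second-largest eigenvalue of U(i,j) = Σₖ P(i,k)P(j,k)/(Pₓ(i)P_y(k))
(`mcc_sqrt` for the square-root variant); rows/columns with zero marginal
are removed before forming U and eigenvalues with imaginary residuals above
1e-8 are discarded. Zero-denominator policies: correlation := 0 when
σₓσ_y = 0; information correlation A := 0 when max(Hₓ, H_y) = 0. Energy and
angular 2nd moment share the formula ΣP² and are reported under both names
to keep the 18-name battery intact.

Offsets are lattice steps; voxel anisotropy is ignored (no distance
correction), a known limitation. Offsets with no valid pair in a small ROI
are excluded from the mean/range aggregation with a warning; aggregation
over a single surviving offset returns (value, 0).

## The Q statistic

Q(f; r) is the ratio of two standard deviations: the spread across N cases
of the condition-minus-reference feature differences (reproducibility), over
the spread across M repeat-contour pairs of the feature at the reference
(repeatability). S is the sample (n−1) standard deviation by default
(`ddof=0` switches to the population convention; the same convention is used
for the mean/std columns of the ranking tables). The numerator uses all N
cases; the denominator only the M cases with a repeat contour. Entries whose
repeatability spread is exactly zero are excluded from rankings and reported
separately rather than treated as infinite.

Rankings sort by the count of Q ≤ 1 (descending) and break ties by
**descending** max Q, then by label. The descending tie-break looks
counterintuitive but is the internally consistent reading of the tabulated
orderings this analysis follows; it is isolated in one place
(`rank_features` / `rank_conditions`).

## Synthetic data model

The generator produces data with the statistical structure the analysis
assumes; it is a phantom model, not a scanner simulation.

**Kernels and noise.** A reconstruction kernel is a pair (psf_sigma,
noise_gain): the in-plane spatial correlation scale of the noise (voxels)
and its relative magnitude at fixed dose. Through-plane correlation is a
kernel-independent 0.3 voxels (slice profile), so the noise field is
anisotropic, as real CT noise is. Within each family, sharper kernels have
larger gains (B10f 2.0/0.50 → B70f 0.3/2.00; I26f\5 1.6/0.45 → I70f\1
0.35/1.60); iterative kernels carry a noise discount relative to comparably
sharp FBP kernels. These are qualitative surrogates — no NPS/MTF data exist
to validate them against, and they are config-editable. Noise fields are
white Gaussian noise convolved with the Gaussian PSF (periodic boundaries)
and rescaled by the exact kernel L2 norm, so the field variance is exact
rather than estimated. Noise magnitude is sigma_ref · gain / √(dose
fraction); reduced doses can equivalently be simulated by adding correlated
noise with variance sigma_ref²·gain²·(1/to − 1/from) to a higher-dose image
(image-domain surrogate; the variance-additivity property is tested). The
noise model is Gaussian and stationary: photon-starvation streaks and
attenuation-dependent nonstationarity are out of scope (see Limitations).

**Reference noise level.** Two anchors, by mode: the water phantom uses
sigma_ref = 10 HU at B45f/full dose (a plausible QA-phantom magnitude; the
phantom analysis only compares conditions, so only ratios matter there).
The nodule study uses 30 HU — thin-slice (1 mm) chest CT at ~21 mGy is
substantially noisier than a water-phantom average — and here the absolute
level matters: the repeatability denominator of Q is set by contour
geometry and nodule/lung contrast, not by the noise, so the ratio of
condition effects to re-contouring effects depends on the absolute noise
magnitude.

**Phantom.** A water cylinder at 0 HU in −1000 HU air; five 10 mm spherical
ROIs are placed by seeded rejection sampling inside a configurable interior
margin (placement pattern is otherwise unspecified). Sphere membership is
the closed ball (voxel center distance ≤ radius): a 10 mm sphere at 1 mm
spacing contains exactly 515 voxels, and the voxelized volume converges to
(π/6)d³ with refinement.

**Nodules.** Ellipsoids with longest in-plane diameter lognormal (median
16 mm, mean ≈ 18 mm, clipped to 7–46 mm), random aspect ratios (0.7–1.0),
per-case mean density N(40, 25) HU in −800 HU textured lung background. The
interior texture is a per-case anisotropic two-scale correlated Gaussian
field with a quadratic skewing transform (correlation ~2 voxels and ~6
voxels, per-axis anisotropy factors 0.6–1.6, coarse fraction 0.2–0.6, skew
0–0.6, magnitude 30–70 HU): real nodules are heterogeneous at several
scales with asymmetric HU histograms, and these per-case properties give
each case its own response to acquisition noise — a single-scale isotropic
Gaussian field makes many texture features nearly condition-invariant and
the robustness analysis degenerate. A per-case noise magnitude factor
(lognormal, σ_log = 0.25) emulates patient-size/TCM variation. The study
config applies a 0.7-voxel partial-volume edge blur (≈1.6 mm FWHM); the
bare generator default is a sharp boundary so that noiseless, textureless
nodules are exactly piecewise constant.

**Contours.** The study contour is the 26-connected supra-threshold
component containing a seed click, thresholded by Otsu over a local box
(256 equal-width bins; at a plateau of the between-class variance the
middle cut is taken, so bimodal samples split at the midpoint). Repeat
contours are modelled by independent boundary flips: each boundary voxel is
removed and each adjacent background voxel added with probability
`flip_prob`; voxels in the eroded core are never removed, so the result is
nonempty. The default flip_prob = 0.2 yields ~15–20% symmetric-difference
fractions, consistent with reported inter-observer variability of
semiautomatic lung-nodule contours.

**Seeding.** One master seed; every volume, contour and perturbation draws
its own seed by hashing (master, case, condition, role), so studies are
reproducible file-by-file and anatomy is shared exactly across the
conditions of a case while acquisition noise is not.

**Study layouts.** The in-memory pipeline (`run_study`) and the on-disk
layout (`generate_study` → NIfTI volumes/masks + `manifest.json`,
`extract` stage reading it back) produce the same feature tables; CSV
outputs are bit-identical across reruns of the same config.

## What the synthetic study shows — and does not

With the default conditions (33 cases, 17 repeat contours, 12-condition
nodule grid), across master seeds: the histogram mean attains Q ≤ 1 in all
11 non-reference conditions (its max Q stays well below 1 — CT numbers are
mean-calibrated and zero-mean noise averages out over the ROI), histogram
entropy and energy are among the least robust features (Q up to ~6 at 3%
dose), and the three 3%-dose conditions always occupy the last three ranks
of the condition ranking.

Two caveats delimit what this reproduces of real-data behaviour:

* **Direction-range degeneracy.** GLCM features that depend only on the
  marginal distribution (mean, sum average, variance) have a directional
  range driven almost entirely by which boundary voxels participate per
  offset. Under stationary Gaussian noise and per-ROI min–max quantization
  (which normalises away the intensity scale), these range features barely
  respond to dose/kernel changes, so they remain robust at every condition
  and tie with the histogram mean in the robust-count ranking. In real
  low-dose CT their condition response comes from streak artifacts,
  nonstationary noise and irregular spiculated contours — all outside this
  generator. The synthetic study therefore reproduces the headline
  qualitatively (mean maximally robust; 3% dose worst) but not the strict
  uniqueness of the mean at the top of the ranking.
* **Repeat-contour surrogate.** Boundary flips exchange contour voxels with
  lung background; under min–max quantization the resulting shift of the
  ROI minimum dominates the repeatability spread of the GLCM features
  (freezing the quantization range shrinks e.g. the contrast repeat spread
  ~5×). Human re-contouring perturbs the intensity range less. The flip
  probability and the nodule-mode noise anchor were calibrated so that the
  repeatability spread is nonzero but small relative to the strong
  (3%-dose) condition effects, which is the regime the analysis is designed
  for.

## Numerical choices

* Quantization bin edges: label = ⌊(v − min)/width⌋ + 1 clipped to [1, L],
  width = (max − min)/L; the top edge is right-closed.
* Otsu: 256 bins, exhaustive between-class-variance scan, plateau-midpoint
  tie-break.
* GLCM accumulation is a vectorised bincount over shifted masks; the test
  suite proves equivalence with a brute-force pair-enumeration oracle to
  1e-9, feature by feature, including the eigenvalue-based MCC.
* Placement of spherical ROIs is rejection sampling with a bounded attempt
  budget (placement-infeasible error beyond it); sphere centers snap to
  voxel centers so voxel counts are deterministic.
* Eigen-solver residuals: complex parts < 1e-8 are treated as numerical
  noise in the MCC.
* Problem sizes: the default study simulates each case in a bounding box of
  its nodule plus an 8-voxel margin at 1 mm spacing (volumes of roughly
  30³–60³ voxels), which preserves the ROI statistics that drive the
  analysis while keeping a full 33-case, 12-condition study fast enough to
  run routinely (seconds, not hours).

## Limitations

* No sinogram synthesis or reconstruction: kernels act only on the noise
  (magnitude + correlation), not on edges/resolution; dose reduction is an
  image-domain surrogate for sinogram-domain noise injection.
* Stationary Gaussian noise; no streaks, no TCM modelling.
* Ellipsoidal nodules with random-field texture; no spiculation, cavitation
  or attached vasculature.
* Repeat contours are a stochastic surrogate for human re-contouring, with
  the behaviour described above.
* Kernel parameters are qualitative; they reproduce orderings (smoother ⇒
  quieter, IR ⇒ noise discount), not any scanner's NPS/MTF.
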