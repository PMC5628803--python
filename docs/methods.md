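# Methods

`alffpipe` implements a resting-state fMRI analysis centered on the
amplitude of low-frequency fluctuations (ALFF): from 4D BOLD series
through nuisance regression to normalized ALFF maps, cluster-corrected
three-group inference, and brain–behavior correlation. Because no real
acquisitions ship with the package, a synthetic-cohort generator with
known ground truth is a first-class component: every downstream stage is
validated by parameter recovery against quantities the generator planted.

## The phantom and what it does (and does not) emulate

Each subject is a small 4D volume (default 24×24×12 voxels of 3 mm,
240 volumes at TR = 2 s — an 8-minute acquisition). The anatomy is
deliberately schematic: a centered ellipsoidal "brain", a gray-matter
shell, a white-matter-like core, a small CSF-like ventricle, and an
out-of-brain shell just beyond the brain boundary. These five
compartments exist so that masking, CompCor noise-ROI pooling and
gray-matter analysis masks all have distinct, non-trivial supports.

Per gray-matter voxel the signal is

    y(t) = baseline + Σ_j (A/m) sin(2π f_j t + φ_j) + drift·t + ε(t)

with m oscillators (default 3) whose frequencies are drawn uniformly in
the 0.008–0.09 Hz band (a bin-aligned debug mode draws exact Fourier
bins, enabling machine-precision spectral oracles), random phases, a
linear drift, and AR(1) Gaussian noise (default marginal SD 2, lag-one
correlation 0.3 — the minimal temporally correlated model that stresses
the band restriction). The per-voxel amplitude A is a region property:
`region base amplitude × group multiplier × subject-level jitter`
(lognormal-free 10% Gaussian jitter, truncated at zero). The group
multiplier is the planted effect; the subject record stores the realized
true amplitudes, withheld from the pipeline. Noise-compartment voxels
carry a shared smooth confound waveform (for CompCor recovery tests) with
±10% voxelwise weight jitter; a config knob optionally leaks the confound
into gray matter to exercise end-to-end confound removal. Brain voxels
outside gray matter oscillate weakly (20% of background) so the brain
mask is not silent.

Motion is a clamped Gaussian random walk on the six rigid parameters
(step SD in mm / degrees, clamp ±1 mm / ±1°), converted to per-volume
rigid affines. Ages are uniform in each group's range; neurocognitive
scores are Gaussian with optional linear coupling to a named region's
true amplitude; white-matter-lesion counts are drawn so that a configured
fraction of subjects exceeds the pathological rule (more than one lesion
per decade of age).

Not emulated: anatomy, registration (subjects are generated pre-aligned
on a common grid and the pipeline asserts the shared `space_tag` rather
than registering), susceptibility or spike artifacts, k-space physics,
physiological cycles with realistic spectra. Consequently, passing tests
demonstrate correctness of the estimators and calibration of the
inference under the stated noise model — not robustness to registration
error or to structured physiological noise.

## Preprocessing

Stage order: discard (default 2 of 240 volumes) → slice-timing
correction → motion QC → grand-mean intensity normalization (target
10 000) → spatial smoothing (default FWHM 8 mm, interpreted as the usual
FWHM convention) → CompCor component extraction → nuisance GLM. CompCor
components are extracted from the *unsmoothed* series so smoothing cannot
mix gray-matter signal into the noise compartments.

- **Slice timing**: slices are assigned acquisition offsets
  `rank/n_slices · TR` (sequential ascending by default; the order is a
  parameter) and every slice is linearly interpolated to the volume
  midpoint (`ref_fraction = 0.5`), clamping at the first/last volume.
- **Motion QC** uses the closed-form RMS displacement of a solid sphere
  (radius 80 mm, centered at the origin of the affine frame) under the
  relative rigid transform: RMS² = (R²/5)·tr(QᵀQ) + ‖Qc + Δt‖². Subjects
  whose worst volume-to-reference RMS exceeds 1.5 mm are excluded.
- **CompCor** pools all noise-compartment voxels, removes each voxel's
  mean and linear trend, scales to unit variance, and returns the top
  5 left singular vectors (orthonormal component time courses). Sign
  convention: each component's largest-magnitude element is positive.
  Combined pooling across compartments is the default; per-compartment
  PCA would be a straightforward variant but is not needed by any test.
- **Nuisance GLM**: 17 regressors — 6 motion parameters, their backward
  differences (first row zero), 5 CompCor components — plus an internal
  intercept that is not counted. All-zero or duplicate columns (which
  legitimately arise for motionless phantoms) are pruned with a warning;
  a rank-deficient design after pruning is an error naming the columns.
  Each in-mask voxel's OLS residual gets its temporal mean added back so
  that amplitude normalization downstream remains well defined.

## ALFF

Per voxel the series is mean-removed and linearly detrended (drift
otherwise leaks into the lowest bins), Fourier transformed, and the
one-sided amplitude `a_k = 2|X_k|/T` averaged over bins with
`f_lo ≤ k/(T·TR) ≤ f_hi` (inclusive edges). With this convention a pure
bin-aligned sinusoid of amplitude A contributes exactly A at its bin; for
the standard protocol (T = 238, TR = 2 s, band 0.008–0.09 Hz) the band
holds bins k = 4…42, i.e. 39 bins, so a single planted oscillator yields
ALFF = A/39. Subject maps are normalized by the whole-brain in-mask mean,
making the in-mask mean exactly 1 and canceling any global intensity
scale (verified to 1e-9 through the whole preprocessing chain).

Numerical caveat, deliberate: the linear detrend is not spectrally
inert — the least-squares slope of a finite sinusoid sample is nonzero,
and subtracting the fitted line redistributes a few percent of a pure
tone's amplitude across bins. Exact-recovery oracles therefore disable
the detrend (the quiet phantom has zero drift by construction); with
detrending on, the A/39 identity holds to within ~10%. An explicit ideal
band-pass stage exists for fidelity but is mathematically redundant when
the band restriction is applied at the bin level (tested for
equivalence).

## Group statistics

- **Within-group**: voxelwise one-sample t against 1 (the normalized
  global mean), df = n−1. Zero-variance voxels get a signed infinite
  statistic, are logged, and are excluded from clustering.
- **Between-group**: voxelwise ANCOVA — OLS of ALFF on group indicators
  plus age; the group F is the extra sum of squares over the age-only
  model with df = (g−1, n−g−1). Two-group F equals the squared group-
  coefficient t (tested against statsmodels per voxel). Post-hoc
  pooled-variance two-sample t maps (Welch optional) are computed inside
  the mask of significant ANCOVA clusters; positive means first group
  larger. Whether post-hoc tests should re-adjust for age is left off by
  default (configurable), matching the common practice of age adjustment
  at the omnibus stage only.
- **Cluster-extent correction** (AlphaSim-style): the null distribution
  of the largest suprathreshold cluster is simulated on the analysis mask
  by filling the grid with unit Gaussian noise, smoothing to a stated
  FWHM (mm), re-standardizing within the mask, thresholding at the
  per-voxel p, and labeling face-adjacent (6-connectivity) components;
  the extent threshold is the smallest k with empirical
  P(max ≥ k) ≤ alpha. The marking policy must match the map being
  corrected: t maps are thresholded two-sided with signs clustered
  separately, so the null marks each sign at p/2; F maps are one-sided at
  p. Smoothness is a stated parameter (protocol value 4 mm), not
  estimated from residuals.
- **WMH second level**: within each significant cluster, a two-sample t
  between lesion-positive and lesion-negative patients, with sub-cluster
  extraction at the same voxel p and extent rule.

Two numerical facts about the correction worth knowing. First, the
attained familywise rate is quantized: cluster extents are integers, so
the attained alpha is P(max ≥ k_min), which can sit well below the
nominal alpha when the tail is lumpy. On the default gray mask at
FWHM 0 the tail crosses 0.05 between extents 5 (P ≈ 0.048) and 6
(P ≈ 0.010); resolving that boundary requires many null iterations
(the calibration experiment uses 1e5; an under-resolved tail flips the
integer threshold and shifts the attained rate several-fold). Second,
matching the null FWHM to the *data* smoothing is only approximate for
statistic maps: an F field built from smoothed Gaussian data is less
smooth than the data themselves (squared-correlation effect), so a
4 mm-matched null over-estimates cluster sizes and is conservative.
This is a known limitation of Gaussian-field Monte-Carlo correction, not
of this implementation; the calibration experiment therefore uses
unsmoothed maps with an unsmoothed null, where the match is exact.

## Brain–behavior

Scores on which the patient group is significantly lower than controls
(per-score unadjusted two-sample t, one-directional rule) are correlated
(Pearson, two-sided p from the t transform with df = n−2) with each
significant cluster's mean ALFF across all subjects pooled. The full
cluster × score family is corrected by Benjamini–Hochberg step-up FDR
(`statsmodels` behind the package surface; an exhaustive definition-based
oracle validates it on random instances). Missing scores are dropped
pairwise with n reported per row. The lesion rule is strict: a count is
pathological iff it exceeds age/10.

## Problem sizes and defaults used by the validation experiments

The calibration experiment uses 200 replicate null cohorts (3 groups × 8
subjects on the default grid), chosen so the binomial CI at the nominal
0.05 rate is informative while the full run stays in the minutes range.
The recovery experiment uses 25 replicates of 12 patients vs 12 controls
with a 50% amplitude increase in a 30-voxel region — an effect size at
which detection should be near-ceiling, so the Dice ≥ 0.5 criterion
tests localization rather than raw power. Monte-Carlo extent thresholds
use 1e5 null iterations in the calibration experiment (tail resolution,
see above) and 5e3 elsewhere; the pipeline default is 1e4.

## Known limitations

- Registration, B0 unwarping, and template normalization are out of
  scope; real data would need them upstream.
- The AR(1)-plus-oscillators noise model has no 1/f continuum or
  physiological peaks; ALFF noise floors in real data are higher and
  frequency-dependent.
- The Gaussian-field Monte-Carlo correction inherits the classic
  smoothness-mismatch approximation for statistic maps (see above).
- Welch post-hoc df uses the median voxelwise Satterthwaite df when the
  unpooled option is chosen, a simplification acceptable for map-level
  thresholding.
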