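# Methods

This note documents the models, parameter choices and known limitations of
`pezmap`, in the order data flows through the pipeline.

## Working grid and volumetry

All volumes live on a 1 mm isotropic lattice (clinical data would be
resampled to 256 × 256 × 220; phantoms are generated directly on the working
grid, 96³ by default). Geometry is computed in voxel space — at 1 mm
isotropic, voxel units and millimetres coincide — and volumes are obtained by
voxel counting at 1 mm³ per voxel, with no partial-volume correction at mask
edges. Resampling uses linear interpolation for parametric maps and nearest
neighbour for masks (preserving binarity), with out-of-field voxels set to 0.

## rCBV reconstruction

The spin-echo DSC signal model S(t) = S₀·exp(−TE·C(t)) is inverted
voxel-wise, C(t) = −(1/TE)·ln(S(t)/S₀), with S₀ the mean of the first five
pre-bolus frames (configurable; the acquisition provides 60 frames at 1.8 s,
TE = 29 ms). Concentration units are arbitrary (proportional to ΔR2); only
the integral ratio matters. Voxels with non-positive signal inside the brain
cannot be log-converted; they are zeroed, counted and reported.

The arterial input function is estimated per transverse slice: candidate
vascular voxels are the in-mask voxels whose peak concentration reaches the
98th percentile of in-mask peaks (background air would corrupt the
percentile, hence in-mask only), a minimum of ten voxels is enforced by
falling back to the ten largest peaks, and the AIF is the per-timepoint
median over candidates smoothed with a Gaussian of σ = 1 time point
(reflection boundaries). rCBV is the trapezoidal integral of the voxel curve
over the trapezoidal integral of the slice AIF, over the full acquisition.

Numerical and policy choices:

- Slices with too few in-mask voxels for an AIF (thin apex slices) borrow
  the nearest valid slice's AIF rather than being dropped, which would bias
  rim coverage; borrowed slices are recorded in the AIF provenance.
- Negative concentration excursions (noise) are kept in the integral; a
  `clamp_negative` option exists but is off by default, so the stated
  formula is reproduced literally.
- A slice whose AIF integral is non-positive is excluded with a warning; a
  volume with no valid AIF at all is an error.

No deconvolution, leakage correction or ΔR2* nonlinearity is applied: the
estimate is deliberately the semi-quantitative integral ratio.

## PEZ geometry

The peri-enhancing zone is {v ∈ brain : 0 < d_E(v, core) ≤ w} with w = 5
voxels and d_E the Euclidean distance transform (a Chebyshev dilation would
over-thicken diagonals; Euclidean distance approximates a surface offset of
the 3D core contours on the voxel lattice). Defining distance from the whole
core set means necrotic interior voxels can never appear inside the rim even
for non-convex cores.

Fluid exclusion precedes partitioning, so reported compartment volumes
exclude fluid. The threshold is per-case: the automated suggestion builds
the rim's ADC histogram (25 × 10⁻⁶ mm²/s bins, Gaussian-smoothed with
σ = 3 bins), finds the parenchymal mode (largest peak below
2000 × 10⁻⁶ mm²/s) and any fluid mode above it, and returns the deepest
valley between them; a unimodal histogram falls back to the conventional
2000 default. A fixed threshold can be supplied instead — the automated rule
replaces the manual per-case histogram inspection used in clinical practice.

Partition membership is voxel-wise overlap with the FLAIR mask and the
recurrence mask (any overlap counts; no minimum overlap fraction). The four
compartments are disjoint and tile the cleaned rim exactly — enforced as a
data-structure invariant, not just tested.

## ROI statistics and cohort normalization

Per-ROI statistics are the voxel mean, the SD (ddof = 1), and two trimmed
means: mean_high excludes voxels at or below the ROI's 20th percentile,
mean_low excludes voxels at or above the 80th percentile. Percentiles use
the linear-interpolation convention (stated because trimmed means of small
ROIs depend on it); ties at the cut are excluded together with the trimmed
tail, making the statistic deterministic. An empty ROI yields NaN statistics
flagged undefined, never zeros. A fully constant ROI is its own trimmed
mean.

Cohort normalization maps each case's within-brain (1st, 99th) percentile
values affinely onto the across-case mean anchors, separately per modality.
Robust percentiles avoid domination by extreme outliers while still spanning
fluid (high ADC anchor) and vessels (high rCBV anchor); the exact percentile
pair is configurable. The transform is strictly monotone, so within-case
value ordering is preserved, and a case corrupted by any affine a·x + b
normalizes to the uncorrupted result. ADC normalization can be switched off
(ADC is already quantitative) but is on by default. Reference-region
normalization against contralateral white matter is deliberately not
implemented.

## Group inference

Each patient contributes both T1+ and T1− compartments, so the primary test
is the paired two-sided Wilcoxon signed-rank on within-patient differences
of compartment means (exact null distribution for small samples without
ties/zeros, normal approximation with tie/zero handling otherwise; zeros
dropped). An unpaired Wilcoxon–Mann–Whitney mode is available. Results with
fewer than five pairs, or with all differences zero, are flagged degenerate.
ADC–rCBV association uses Pearson's r with the t-distribution p-value.

ROC analysis pools the per-case compartment means of the FLAIR+ stratum
(T1+ vs T1− labels; a FLAIR− option exists). AUC uses the rank (Mann–
Whitney) formulation with average ranks, so ties count one half. The
operating threshold maximizes Youden's J over observed values; ties in J are
broken toward higher specificity. For ADC the discriminating direction is
"lower indicates recurrence-prone", handled by a direction flag so the
reported threshold stays on the ADC scale. No multiple-testing correction is
applied; raw p-values are reported.

## Phantom generator

The generator emulates exactly the features the analysis consumes:

- **Geometry.** A spherical brain (radius 40 at the 96³ reference scale,
  rescaled proportionally for other grids); a spherical enhancing core
  (radius 12) with necrotic interior (6) offset from the brain centre; an
  anisotropic FLAIR halo — 10 thick on one hemisphere, 2 on the other, so
  the 5-voxel rim contains both FLAIR+ and FLAIR− tissue; a spherical
  recurrence lobe (radius 8) along an axis orthogonal to the FLAIR axis,
  whose centre offset is solved by bisection so that one third of its
  volume (± a small tolerance) lies outside the FLAIR halo; a ventricle
  ellipsoid abutting the rim plus a 2-voxel sulcal CSF shell; scattered
  vessel voxels outside the peritumoral band. Contiguity of the lobe with
  the core and single-connectedness are enforced, with a generation error
  otherwise.
- **Class means.** ADC (10⁻⁶ mm²/s): FLAIR+ stable 1291, FLAIR+
  recurrence-prone 1192, FLAIR− 971 (both), normal brain 800, fluid 3000,
  core 900, necrosis 2200, vessels 1000. CBV (unitless): 0.29 / 0.33 /
  0.35 / 0.35, normal 0.35, vessels 1.0, fluid and necrosis 0.05, core 0.6.
  FLAIR− contrasts are null by construction: the analysis should find
  nothing there, and small observed FLAIR− differences in any one cohort
  are sampling noise. Core, necrosis, vessel and fluid values are plausible
  fillers — they are never analysed, only excluded or used for anchoring.
- **DSC synthesis.** Tissue concentration is cbv · scale · b(t) with a
  gamma-variate bolus b (arrival 18 s, shape α = 3, time-to-peak 9 s, unit
  peak), passed through S(t) = S₀·exp(−TE·C(t)) at S₀ = 1000 with additive
  Gaussian signal noise (SD 2). Vessels carry unit amplitude, so recovered
  tissue rCBV is directly comparable to the class table and integral ratios
  between classes are analytically known. The vessel density (12 % of the
  eligible extra-peritumoral tissue) is deliberately higher than anatomical
  reality: the slice-wise 98th-percentile AIF selector needs vascular
  voxels to exceed 2 % of every analysed slice.
- **Between-subject variability** (per-case class-mean draws) has a shared
  peritumoral component (ADC SD 140, CBV SD 0.056) with negative ADC–CBV
  coupling (ρ = 0.8), reproducing the across-patient ADC–rCBV
  anticorrelation, plus independent per-class deviations (ADC SD 105, CBV
  SD 0.05) that set the paired-test power: at n = 46 the standardized
  FLAIR+ contrasts are ≈ 0.6, giving the paired signed-rank test > 95 %
  power, while marginal across-case SDs land at realistic clinical spreads
  (≈ 175 for ADC, ≈ 0.075 for CBV). A per-case global gain/offset on the
  ADC map (SD 4 %, 25) emulates acquisition variability and is what the
  cohort normalization removes.
- **Voxel noise** is i.i.d. Gaussian around class means (ADC SD 150, CBV
  SD 0.04). No spatial texture, anatomy, susceptibility artifacts or motion
  are modelled; passing tests demonstrate correctness of the computational
  chain under the stated model, not robustness to real-data confounds such
  as spatially correlated noise, imperfect registration or segmentation
  error.

Determinism: a case is bit-reproducible from (spec, seed); cohorts derive
per-case seeds and jittered geometry (± 10 % radii, random orthonormal
lobe/FLAIR axes) from a single master seed.

## Problem sizes used in the checks

Desk-scale validation uses 48³ phantoms; the cohort-recovery check runs the
full pipeline on 46 cases at 96³ (the package's default study scale), and
type-I control uses 200 null-effect cohorts of 46 cases at 48³, diffusion
arm only. The full 256 × 256 × 220 working grid is supported behind a flag.

## Known limitations

- The AIF scheme assumes some voxels in every slice are strongly vascular;
  slices where vessels fall below the percentile cut yield a
  tissue-dominated AIF and locally inflated rCBV.
- Only local, core-contiguous recurrence is modelled; multifocal or distant
  recurrence would require a different seed volume.
- The near (5–10 mm) and far (10–15 mm) peritumoral zones are out of scope.
- Masks are inputs: skull stripping, tumour segmentation and
  baseline–follow-up registration are upstream of this package.
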