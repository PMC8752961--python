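# Methods

## Problem and model

Multi-compartment diffusion-MRI models decompose each voxel's signal
into a free-water (CSF) compartment and a tissue compartment, yielding
tissue-space metrics (NDI, ODI, or analogous quantities from free-water
elimination fits) plus the tissue volume fraction TF = 1 − FWF. The
metrics describe only the tissue inside a voxel, while the amount of
tissue varies across voxels. An ROI summary should therefore estimate
the mean metric over the region's *tissue*, not over its voxels.

Writing mᵢ for the metric and tᵢ ∈ [0, 1] for the tissue fraction of
voxel i in an ROI of N voxels, the package computes

- conventional mean: m̄ = (1/N) Σ mᵢ,
- tissue-weighted mean: m̄ₜ = Σ tᵢ mᵢ / Σ tᵢ, equivalently
  mean(t·m)/mean(t),

and the exact decomposition m̄ − m̄ₜ = −Cov(m, t)/t̄, where Cov uses the
1/N (population) normaliser. This is an algebraic identity, not an
approximation: expanding mean(t·m) = t̄·m̄ + Cov(m, t) and dividing by
t̄ gives it directly. Consequences used throughout:

- the two means coincide iff Cov(m, t) = 0 (e.g. constant TF);
- negative metric/TF correlation inflates the conventional mean and
  vice versa (sign rule);
- at fixed covariance, |bias| scales as 1/t̄, so CSF-contaminated
  (periventricular, atrophic) regions are worst affected.

The tissue-weighted mean assumes the voxel metric is the tissue-volume-
weighted average of the underlying tissue property over the voxel, and
that TF estimates the tissue volume fraction without systematic error.
Under those assumptions it is exact under spatial aggregation: if voxels
are block averages of a fine tissue/CSF grid, Σ tᵢ mᵢ equals the sum of
the property over all tissue sub-elements and Σ tᵢ the tissue volume, so
m̄ₜ recovers the fine-grid tissue mean identically. The phantom module
verifies this to floating-point precision. The ROI *median* is included
for comparison only: it carries bias of the same order as the
conventional mean and is not a correction.

## ROI extraction

Inputs are already-fitted scalar NIfTI maps and an integer label image
on one grid (registration and atlas propagation are upstream). Grids
must match in shape exactly and in affine to 1e-4 elementwise —
loose enough for header round-trip noise, tight enough to catch a wrong
space. Free-water maps are converted as TF = 1 − FWF; FWF values within
±0.01 of [0, 1] are clipped with a warning, anything further out is
rejected as not a fraction map. Voxels with non-finite metric *or* TF
are excluded pairwise, so both estimators always see the same voxels —
this keeps the bias identity exact on extracted samples. TF values
outside [0, 1] (imperfect fits) are clipped by default, with a warning
and an opt-out. An all-CSF ROI (Σt = 0) raises rather than returning
NaN, and regions defined in the atlas table but missing from a label
image are reported, not dropped silently.

The packaged ROI table is the JHU ICBM-DTI-81 white-matter parcellation
(integer labels 1–48) with a periventricular flag per region (29
periventricular, 19 not); it ships as CSV so other atlases can be
substituted.

## Group analysis

The workflow operates on a long-format cohort table (one row per
subject × region × metric) and mirrors standard two-group ROI practice:

- **Mean TF comparison**: per region, two-tailed Welch t-test on the
  per-subject mean TF between groups (mean TF is metric-independent and
  deduplicated first).
- **Bias tests**: per region × metric, one-sample t-tests of the
  per-subject bias against zero within each group, and a Welch test of
  bias between groups.
- **Bias correlates**: Pearson correlation between per-region
  between-subject mean |bias| and mean 1/TF (the identity predicts
  proportionality), and a Welch comparison of mean |bias| between
  periventricular and non-periventricular regions, decided at
  uncorrected α.
- **Effect sizes**: Cohen's d_s — pooled, Bessel-corrected SD, no
  small-sample (Hedges) correction — computed per region × metric twice,
  once from conventional and once from tissue-weighted means, with the
  difference exposing estimation-driven distortion of group effects.

Statistical conventions: the t-tests and d_s are implemented from their
formulas (with `scipy.stats.t` for tail probabilities) and are
cross-checked against SciPy and pingouin in the test suite to 1e-10.
The Bonferroni family is the set of regions within one metric × test
combination — families are not pooled across metrics — and is recorded
in the output metadata. The contrast is "reference minus comparison",
defaulting to the first-listed group. Degenerate inputs follow a p = 1
convention when both sides have zero variance *and* equal means (the
test is vacuous), and raise otherwise; zero pooled SD makes d_s
undefined and raises. Welch degrees of freedom are fractional
(Welch–Satterthwaite). Correlations use per-region group means of
|bias|, one observation per region (bilateral regions are separate
observations), and require ≥3 regions and non-constant inputs.

The workflow is exposed both as functions and as a model-style wrapper:
`GroupAnalysis(cohort, ...).fit()` returns a `GroupAnalysisResults`
holding all tables plus metadata, with `summary()` and `save()`.

## Synthetic data

Two generators provide ground truth that real data cannot.

**Fine-grid phantoms.** A density field on a fine grid with a CSF mask,
block-averaged by an integer factor into "acquisition" voxels: per
voxel, TF = fraction of non-CSF sub-elements, metric = mean density over
them (fully-CSF voxels are excluded — they carry no tissue metric). CSF
probability and density both vary linearly along one axis with
controllable slopes, so the sign of the voxelwise metric/TF covariance
is constructed, not assumed. These phantoms test the aggregation
exactness and the sign rule.

**Parametric cohorts.** Per region, tissue fractions are drawn from a
Beta distribution parameterised by mean and SD (bounded support matches
a volume fraction; means and spreads are configurable per region and
group). The noiseless metric is m₀ = μ + κ·(t − t̄), so the population
covariance is exactly κ·Var(t) and the predicted bias −κ·Var(t)/t̄ is
analytic; Gaussian voxel noise (SD σ) is added and the result clipped to
[0, 1], with a warning if clipping exceeds 5% of voxels. Within one
subject and region a single TF vector is shared by all metrics, as a
subject has one TF map. Subject-level heterogeneity enters through
Gaussian shifts of μ (SD `between_subject_sd`) and of the TF mean (SD
`tf_between_sd`); two-sample tests need this between-subject variance to
be realistic.

The default cohort mirrors a typical atrophy study: 21 control vs 30
patient subjects, all 48 packaged regions at 100–1000 voxels each on a
32³ grid of 2.5 mm voxels. Control mean TF spans ~0.70–0.88 in
periventricular and ~0.88–0.97 in non-periventricular regions; patients
sit 0.05–0.08 (periventricular) or ~0.015 (non-periventricular) lower.
κ(ODI) is negative everywhere and more negative in patients and in
periventricular regions (ODI over-estimated by the conventional mean,
worst where TF is low); κ(NDI) is mildly negative in
non-periventricular regions and alternates in sign across
periventricular ones (mixed bias direction). Voxel noise SD is 0.05 and
between-subject SD 0.025, typical scales for regional NODDI metrics.
Per-region parameters are varied deterministically (a golden-ratio
sequence over the region index) so the recipe itself contains no hidden
randomness; ground truth (noiseless tissue mean, covariance, mean TF)
is recorded per subject × region × metric at generation time. Cohorts
can be written as NIfTI volumes plus a shared label image carrying the
atlas label ids, and regeneration from the same config and seed is
byte-identical.

What the generator does **not** emulate: spatial autocorrelation of
noise and anatomy within regions, NODDI fitting error structure
(noise is Gaussian and independent of TF given the mean), registration
and interpolation effects of template-space analysis, age/sex
covariates, and non-Beta TF distributions such as hard ventricle
boundaries. Passing tests therefore validate the estimators and
inference machinery under a controlled generative model, not the
upstream imaging pipeline.

## Numerical and design choices

- Population (1/N) covariance everywhere; N = 1 gives covariance 0 and
  hence zero bias, consistent with both means equalling the single
  voxel's value.
- Even-length medians use the midpoint convention.
- The two tissue-weighted formulations agree to ≈1e-16 relative in
  practice; tests bound them at 1e-14, and the bias identity at 1e-12
  absolute.
- Voxel traversal order never affects any statistic (summation is over
  unordered sets; tests permute storage order).
- All randomness flows through `numpy.random.default_rng`; cohort
  generation, the CLI and the acceptance script take explicit seeds and
  are bit-reproducible, which an end-to-end checksum test pins.
- Exit codes: 0 success, 1 analysis error (bad data), 2 usage/config
  error.

Problem sizes used by the validation suite — 10,000 random samples for
the identity bounds, 100 phantoms for exactness/sign checks, 10 TF
levels × 20 regions for the inverse-TF proportionality, one 21-vs-30
cohort for effect-size recovery, and 1000 replicate 48-region null
cohorts for calibration — keep the full suite and the acceptance script
in the tens of seconds while leaving Monte-Carlo margins wide relative
to the tolerances tested.

## Known limitations

- The correction targets the ROI *summary*; voxelwise metric values are
  taken as given, and no per-voxel partial-volume correction is
  attempted or needed for it.
- TF estimation error propagates into the weights; systematic TF bias
  would bias the tissue-weighted mean, and the package does not model
  it.
- The group workflow implements two-group designs only; covariate
  adjustment (age, sex) and FDR/permutation alternatives to Bonferroni
  are out of scope.
- Label images must already live on the metric grid; no resampling is
  performed.
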