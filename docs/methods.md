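# Methods

`peritex` re-implements, as a reusable and tested library, the classic
single-slice CT radiomics workflow used to separate infiltrated peritumoral
tissue (high-grade glioma, "HGG-like", the positive class) from purely
edematous peritumoral tissue (brain metastasis, "BM-like"): ROI definition,
MaZda-style texture-feature extraction, two-method feature reduction,
univariate screening, ROC characterization, and a combined linear prediction
model. This note records the model choices, the numerical conventions, and
what the synthetic cohorts do and do not establish.

## ROI definition

The peritumoral zone is a 2D region on a single axial slice. `region_grow`
reconstructs the semi-automatic delineation as a 4-connected flood fill from
a user seed, constrained by three stops: an intensity tolerance around the
seed value (HU), a gradient barrier (central-difference gradient magnitude,
HU/pixel; one-sided at borders), and a geometric radius in millimetres using
the pixel spacing. The true vendor algorithm is not published; this rule is
a *reconstruction* of "gradient and geometric coordinates", not a
reproduction, and manual corrections are modelled as set arithmetic
(`apply_edits`). 4-connectivity is used rather than 8 so the region cannot
leak diagonally through one-pixel rims. Regions under 9 pixels are rejected,
mirroring the clinical exclusion of peritumoral zones narrower than 10 mm.

## Gray-level normalization and quantization

Before feature computation the ROI intensities are remapped to `Ng = 2^bits`
integer levels (bits ∈ {4, 6, 8}). In the default `mu3sigma` mode the window
is `[μ − 3σ, μ + 3σ]` with μ, σ computed over in-mask pixels only (σ is the
population standard deviation, matching the moment definitions of the
histogram features); intensities are clipped to the window and mapped by

    level = 1 + floor((clip(x) − low) · (Ng − 1) / (high − low) + 0.5)

i.e. linear rescaling with half-up rounding — the window is named in the
MaZda tradition but the exact mapping is this package's documented
convention. The mapping is monotone and invariant to affine intensity
transforms, so scanner brightness/contrast settings cancel. A constant ROI
(σ = 0) maps to level 1 everywhere and raises a degeneracy flag instead of
erroring, so cohort runs proceed and mark the subject. Whether the
normalization statistics should be ROI-restricted or whole-image is not
settled in the literature; ROI-restricted is implemented (the MaZda-manual
convention) and the mode is switchable (`full_range`, `fixed_window`).

## Feature classes (275-parameter default profile)

All classes consult the mask, never the out-of-mask sentinel.

* **Run-length matrix** (20 = 5 features × 4 directions, 6 bits): maximal
  equal-level runs along H/V and the two diagonals, truncated at the mask
  boundary; short/long-run emphasis, gray-level and run-length
  non-uniformity, and the fraction of image in runs, each normalized by the
  total run count.
* **Haar wavelet energies** (20 = 4 subbands × 5 scales): dyadic orthonormal
  Haar decomposition (periodized) of the ROI bounding box with out-of-mask
  pixels mean-filled (mean-fill avoids the spurious edge energy of
  zero-fill). Subbands are labelled by the filter along (rows, columns):
  LH = low along rows/high along columns. Energy is the mean squared
  coefficient over coefficients whose support overlaps the subsampled mask;
  scales whose subsampled mask is empty are undefined with a recorded
  reason.
* **Co-occurrence (Haralick) features** (220 = 11 features × 5 distances ×
  4 directions, 6 bits): symmetric accumulation, normalized to sum 1, with
  pairs crossing the mask dropped (the ROI is irregular; padding would
  fabricate texture). Natural logarithm for all entropies; `0·ln 0 ≡ 0`;
  `SumOfSqs` uses the marginal mean per Haralick's original definition;
  `DifVarnc` is the variance of the |i−j| distribution about its own mean.
* **Histogram** (5): mean, variance, skewness, excess kurtosis (population
  moments) of the quantized levels plus the 10th percentile — the smallest
  level holding at least n% of the pixels. The extended profile adds
  percentiles 1/50/90/99. Five histogram features keep the default profile
  at the canonical 275 total.
* **Absolute gradient** (5, 4 bits): central-difference gradient magnitude
  on the coarse level grid at pixels whose full 4-neighborhood is in-mask;
  moments of G plus the nonzero fraction.
* **Autoregressive model** (5): least-squares fit of each pixel on its four
  causal neighbors (left, up-right, up, up-left) after subtracting the ROI
  mean; `Sigma` is the residual standard deviation. Requires ≥ 20 eligible
  pixels; a rank-deficient system (constant ROI) leaves the θs undefined
  with `Sigma = 0`.

### Wavelet normalization mode

The wavelet class is quantized over the ROI's **full dynamic range**
(min–max) rather than the μ±3σ window (profile setting `wavelet_norm_mode`).
Subband energies are meant to measure how fluctuation at each scale fills
the ROI's intensity range; a symmetric ±3σ clip distorts that measurement
for skewed ROIs (exactly the ROIs of interest here, whose infiltration
spikes sit many σ above the mean), and the originating software likewise
treats the wavelet class separately from its normalization option. This is
a deliberate, documented design choice; note that with a single
normalization for every class, a higher co-occurrence contrast at 4–5 px
lags and a higher wavelet detail energy over the same 4–16 px band would be
measuring the same normalized band content and could not point in opposite
directions between the classes.

### Naming

Canonical names are `{CLASS}_{qualifiers}_{Feature}` (`GLCM_H_d4_DifVarnc`,
`WavEn_HH_s2`, `RLM_Z_GLevNonU`, ...). The MaZda-style codes that recur in
clinical reports (`CN6D4Contrast`, `RZD5GLevNonU`, `WavEnHH_s-2`, `Perc10`,
...) are attached as aliases for the seven recurrent parameters; the
mapping reads the leading letter as the direction and `D`/`s` digits as
distance/scale and is flagged non-authoritative, since the encoding is not
published.

## Feature reduction

* **Fisher coefficient**: `F = Σ P_k (μ_k − μ)² / Σ P_k σ_k²` with class
  proportions `P_k` and population within-class variances; scale-invariant,
  `F = 0` for identical class means, `+∞` flagged when the within-class
  variance vanishes with distinct means. Top-k (default 10) features by F,
  ties broken lexicographically for reproducibility.
* **POE + ACC**: features are standardized; POE is the minimal empirical
  misclassification fraction of a single-threshold rule (both polarities
  searched) — the published method names POE but not its classifier, so this
  is the simplest faithful estimator, documented as a reconstruction. The
  greedy selection takes the minimal-POE feature first, then repeatedly
  minimizes `POE(f) + mean |Pearson r(f, s)|` over already-selected `s`,
  with equal weights (the method's name read literally).

A consequence worth knowing: features carrying the *same* class signal are
mutually correlated through that signal (r ≈ d²/4 / (1 + d²/4) for Cohen's
d), so POE+ACC deliberately does not shortlist all of a redundant effect
cluster — that is its purpose, not a defect. Recovery guarantees are
therefore asymmetric: Fisher retrieves an entire planted effect cluster;
POE+ACC retrieves its head and representatives, and the union of the two
shortlists covers the cluster (the property tests assert exactly this).

## Univariate screening

Each feature in the union of the two shortlists is compared between classes
with the Mann-Whitney U test (`U = Σ [x > y] + ½[x = y]`); the p-value is
exact by enumeration for ≤ 16 untied observations and otherwise uses the
normal approximation with tie-corrected variance and continuity correction.
The significance threshold is Bonferroni `α/m` with `m = |union| + 2` by
default — the union of shortlists plus the two clinical covariates (age,
sex) of the study design this mirrors; when covariate columns are supplied,
m counts them instead. The reference study's own recipe (0.05 / 19 for 17
unique parameters + age + sex) gives 0.00263; its text prints 0.0023, and
both thresholds admit the same seven parameters of its univariate table.
The companion "omit predictors with p > 0.01" rule of that design is
contradictory as printed and is implemented only as an optional post-hoc
flagging threshold (default: no omission).

## ROC analysis

AUC uses the rank (Mann-Whitney) formulation, so `AUC = U/(n₊ n₋)` holds to
machine precision. The test against AUC = 0.5 uses the DeLong structural
components variance. The 95% AUC interval is binomial exact
(Clopper-Pearson on the count of correctly ordered pairs out of `n₊·n₋`) —
the convention of the clinical software this mirrors; it is conservative
because pairs are not independent, and the DeLong SE is also reported. The
operating point maximizes the Youden index `J = Se + Sp − 1` over observed
criterion values, taking the lowest criterion on ties; the positive
direction is auto-chosen so AUC ≥ 0.5 and reported as `>t` or `≤t`.
Sensitivity and specificity carry Clopper-Pearson 95% intervals.

## Prediction model

The combined model is an "enter"-type multiple regression: the 0/1 class
outcome regressed by ordinary least squares on *all* significant features
simultaneously (a linear probability model — the coefficient scales and the
0–1 fitted-value criterion of the mirrored study identify MedCalc-style
"multiple regression", not logistic regression). Reported per predictor:
coefficient, SE, t-based p, partial correlation `t/√(t² + df)`, semipartial
correlation `t·√(1 − R²)/√df`, and VIF `1/(1 − R_j²)` from regressing the
predictor on the others. Model-level: R², adjusted R², and the multiple
correlation coefficient `√R²`. Exact collinearity raises an error naming
the dependent columns rather than silently dropping one. The fitted values
feed a final ROC analysis of the combined model.

## Synthetic cohorts

Patient CT slices cannot be redistributed, so the pipeline is exercised on
phantoms that reproduce the *statistical* contrast the analysis assumes.
Each image is `base + field + blobs + noise` on a 128×128 grid (1 mm
pixels): an edema plateau of 8 HU; a Gaussian-kernel-smoothed white-noise
field scaled to unit variance times a class amplitude; for the HGG-like
class only, Poisson-scattered Gaussian blobs; and i.i.d. Gaussian pixel
noise (3 HU — the plateau-level noise of a soft-tissue CT reconstruction).
The ROI is an annulus between an inner "enhancing rim" disc and an outer
margin, ≥ 10 px wide, with jittered geometry; everything is deterministic
given the seed (per-subject seeds are `rng_seed + index`, so cohorts are
stable under resizing).

Default class parameters:

| class | field amplitude | field corr. length | blobs |
|---|---|---|---|
| A (HGG-like) | 5 HU | 0.8 px | 0.3 cm⁻², radius 1 px, 60 HU |
| B (BM-like) | 3 HU | 6 px | none |

These values realize the qualitative structure the generator exists to
emulate, with one mechanism per reported effect family: the rough
short-range field gives class A higher local variance and higher
co-occurrence contrast / difference variance at 4–5 px lags; the sparse
tall blobs make class A's histogram a narrow plateau cluster plus a long
right tail, which raises its normalized 10th percentile and gray-level
non-uniformity and — by widening its dynamic range — *suppresses* its
range-normalized wavelet detail energies, so the smoother, narrow-range
class B runs higher on the scale-2/3 wavelet detail bands. The class-B
field is weaker and longer-range than class A's, as the biology suggests
(displacing edema vs infiltrating cells).

What the phantoms do **not** model: anatomy, partial-volume and beam-
hardening effects, contrast-enhancement kinetics, inter-scanner variation,
or 3D structure. Passing tests therefore establish that the *pipeline*
recovers planted statistical structure of this kind — not that the
particular clinical effect sizes would replicate on new patients.

## Statistical calibration of the workflow

Two Monte-Carlo properties are asserted on synthetic cohorts:

* **Effect directions** — on 100 default cohorts (n = 17/19) the
  group-median directions of the seven reported parameter families match
  the reference pattern in ≥ 90% of cohorts.
* **Family-wise error of the screening stage** — on 200 null cohorts
  (identical class parameters, n = 17/19, 64×64 images; the stage under
  test is label-side, so image size is immaterial) the univariate +
  Bonferroni stage is evaluated against freshly permuted labels and keeps
  its family-wise error inside the binomial band around the nominal 5%.
  The permutation matters: re-testing the very labels the shortlist was
  optimized for measures *selection bias*, not the correction — that design
  (which is also the design of the mirrored study, and of much of the
  radiomics literature) inflates the measured family-wise error to ≈ 20%
  here, because the tested features are the extreme order statistics of
  ~275 correlated candidates while the divisor only counts the ~19 tests
  actually run. Users applying this workflow to real cohorts should treat
  the screening p-values as descriptive unless selection and testing are
  performed on independent data.

* **Monotonicity / parameter recovery** — the combined model's median AUC
  (20 seeds per point, n = 10/10, 64×64) increases with planted blob
  amplitude until saturation, with the two classes otherwise identical so
  the blobs are the only signal; and the causal AR fit recovers a planted
  θ₁ = 0.5 within three standard errors on a 48×48 lattice.

Problem sizes above (cohort counts, replicate counts, image sizes) are the
package's chosen calibration conditions and are fixed in the test suite.

## Numerical conventions and degenerate inputs

Natural log everywhere; population variances throughout the texture
moments; half-up rounding in quantization; lexicographic tie-breaks in both
selection methods; lowest-criterion tie-break at the Youden optimum;
undefined feature values carry a recorded reason and propagate as NaN
without aborting a subject (features undefined for any subject are dropped
from cohort statistics, with counts logged). Degenerate cases — constant
ROIs, empty co-occurrence pair sets, sub-minimal AR neighborhoods, empty
subsampled wavelet masks — are defined above rather than left to chance.

## Known limitations

2D only; single-frame grayscale DICOM with linear rescale only; the
region-growing rule and the POE estimator are reconstructions of
unpublished vendor behaviour; the MaZda alias mapping is best-effort; the
linear probability model can emit fitted values outside [0, 1] (as does the
software it mirrors); and the screening stage's error control assumes the
tested features were not selected on the same labels (see above).
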