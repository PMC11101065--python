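# Methods

## Feature definitions

An 8-bit RGB image with N pixels is summarized by four statistics. The
channel means avg_R, avg_G, avg_B are exact arithmetic means (float64, no
rounding). Grayscale conversion uses ITU-R BT.601 luma,
round(0.299·R + 0.587·G + 0.114·B) with round-half-away-from-zero — the
dominant library convention; the source analysis did not pin a method, so
the package standardizes on this one. One-dimensional entropy is the
Shannon entropy of the 256-bin gray-level histogram,
H = −Σ P_i log2 P_i with 0·log 0 ≡ 0, in bits, over exactly the integer
levels 0–255 (no re-binning). H ∈ [0, 8], with 8 reached only by an
equifrequent 256-level histogram. (Some write-ups of this entropy omit
the leading P_i factor in the summation; the standard Shannon form is
what "average information content" means and is what is implemented.)
Alpha/palette images are converted to RGB explicitly; 16-bit and
floating-point inputs are rejected rather than silently rescaled.

## Cohort statistics

Group summaries are sample mean and SD (n−1 denominator). The two-sample
comparison is the pooled-variance Student t-test, computable either from
raw rows or from (n, mean, SD) cells alone; the two routes share one code
path and agree exactly. Pooled rather than Welch is the default because
the pooled form reproduces the reference cohort's printed t statistics
from its printed summary cells to ≤0.13% (worst row: training-partition
entropy, 34.628 vs the printed 34.653), which Welch does not; Welch
remains available via `welch=True`. The subtraction order is an explicit
argument (`sign_convention` is recorded in the result) because published
tables mix benign-minus-malignant and malignant-minus-benign
conventions.

The train/validation split is simple random and non-stratified, with
|validation| = floor(0.3·N) — the only rule consistent with a 2,723-row
cohort splitting 1,907/816. The seed is a required, recorded input.

## Model fitting and selection

The logistic model is fitted by maximum likelihood with Newton scoring
(equivalent to iteratively reweighted least squares), standard errors
from the inverse observed information; convergence at relative
log-likelihood change < 1e-10 or 100 iterations. Perfect separation and
constant features raise errors rather than returning divergent
estimates. Labels are coded malignant = 1, fixed by the sign structure
of the reference model (entropy is higher in malignant tissue and
carries a positive coefficient). The fit itself is delegated to
statsmodels' Logit; the package's contribution is everything around it.

Variable selection is a univariate pooled-t screen at α = 0.05 followed
by backward elimination of the largest multivariable Wald p ≥ α, with
every step logged. The backward-elimination stage is this package's
documented stand-in for an unstated selection path: the reference model
kept R, B and entropy but dropped G, which a Wald-based elimination can
produce under collinearity (G correlates strongly with R and B in real
stains) but will generally not reproduce on synthetic *independent*
features, where all four predictors carry signal and survive. Pipeline
consumers should therefore expect a three-or-four-variable model
depending on the feature correlation structure.

Wald inference: χ² = (β/SE)² against χ²₁, OR = exp(β), 95% CI =
exp(β ± 1.959964·SE). The multiplier is the exact 97.5% normal quantile
(not 1.96) to match mainstream software output.

## Nomogram construction

For predictor v with coefficient β_v over range [lo_v, hi_v], the
reference value x_ref,v is the low-risk end (lo if β_v > 0, hi
otherwise) and

    points_v(x) = β_v·(x − x_ref,v) / s,   s = max_u |β_u|·(hi_u − lo_u) / 100,

so the dominant axis spans exactly 0–100 points and all axes are
non-negative in range. Total points T map to probability through
σ(η_ref + s·T), where η_ref is the linear predictor at the all-reference
point — an affine re-parameterization, so nomogram scoring equals direct
logistic scoring to machine precision (tested at ≤1e-9). Ranges default
to the observed training min/max; a zero-width range yields a flat
0-point axis with a warning.

## Evaluation

AUC uses the tie-aware Mann–Whitney rank form; the threshold-swept ROC
curve's trapezoidal area equals it identically (asserted at 1e-12 in the
tests, and the implementation is cross-checked against an exhaustive
pair-counting oracle and scikit-learn). The 95% CI is a percentile
bootstrap over case resamples (default B = 1000, seeded); replicates
missing a class are redrawn, with a 100·B total-draw cap. Percentile
rather than normal-approximation intervals because no distributional
assumption is needed and the choice is config-exposed anyway.

Hosmer–Lemeshow groups are equal-frequency quantile bins of predicted
probability (default g = 10) with tied probabilities kept in one group
(so heavy ties reduce the group count); both outcome cells contribute,
χ² = Σ (O₁−E₁)²/E₁ + (O₀−E₀)²/E₀, df = groups − 2; groups with a
vanishing expected cell are merged into a neighbor and flagged. The
calibration curve uses the same binning, one (mean predicted, observed
fraction) point per bin.

Decision curves evaluate NB(p_t) = TP/N − (FP/N)·p_t/(1−p_t) on a 0.01
step grid by default, with treat-all π − (1−π)·p_t/(1−p_t) (crossing
zero exactly at the prevalence π) and treat-none ≡ 0; an optional
case-resampling percentile band mirrors the two flanking lines seen in
published decision-curve figures.

## Synthetic data

The generator's default parameters are the reference cohort's printed
class-conditional means/SDs at 2,214 malignant / 509 benign images
(`chromopath.reference`): malignant avg_R 219.969±5.137, avg_G
202.024±13.060, avg_B 220.340±8.827, H 5.425±0.573; benign avg_R
226.308±6.265, avg_G 219.060±17.180, avg_B 228.996±7.237, H 4.146±0.984.
Features are drawn multivariate-normal per class and clipped to their
valid ranges afterward (clip rates are negligible at these parameters —
the nearest bound is >4 SD away — so clipping is preferred to truncated
sampling for simplicity). The default correlation matrix is the
identity: only marginals were reported, so cross-feature correlations
are unknowable. This matters in two ways. First, with independent
features the three-variable reference coefficients applied as a fixed
score give a closed-form Gaussian linear-score AUC of
Φ(Δμ_s/√(σ²_s,mal+σ²_s,ben)) ≈ 0.778 — the observed-cohort AUC of 0.889
is *not* expected under independence and is not a synthetic-data target.
Second, because the classes have unequal SDs, the true log-odds on these
Gaussians is quadratic, so a linear-logit fit is mildly misspecified and
the Hosmer–Lemeshow test will detect this at large n (as in the demo's
training partition); that is a property of the generator, not a defect
of the test.

The image renderer realizes a target feature vector as pixels: each
pixel draws one latent gray level g i.i.d. from a one-parameter
exponential-family distribution over a W-level window (default W = 64),
p_g ∝ exp(θ·g), with θ solved by bisection so the distribution's entropy
equals the target H (entropy is strictly monotone in |θ|, from log2 W at
θ = 0 toward 0). The tilt is oriented so the mode sits at the window
top: H&E-stained tissue is bright (channel means 200–230), and with the
sparse tail pointing down-range the integer channel offsets
round(target_c − E[g]) stay clip-free for all cohort-typical targets.
Because the luma weights sum to one and the three channels differ from g
by integer constants, the grayscale image is g plus a constant, so
extracted entropy equals the latent entropy exactly up to sampling; the
renderer's contract is channel means within ±1.0 intensity units and
entropy within ±0.1 bits whenever <1% of values clip (a returned flag;
infeasible targets flag rather than raise). `generate_dataset` writes
one PNG per simulated row plus a manifest CSV and is byte-reproducible
given a seed.

What the synthetic data does *not* emulate: spatial structure (nuclei,
stroma, texture), stain variation, JPEG artifacts, within-patient
correlation between images (images are treated as independent,
mirroring the source analysis), and cross-feature correlation. Passing
tests on synthetic data therefore demonstrate correctness of the
statistical machinery under the documented marginals, not expected
performance on real slides.

## Problem sizes and numerical choices

Sampling-based checks use sizes chosen to make their error bounds sharp:
mean recovery at 10,000/class (4·SD/√n bound), correlation nullity at
50,000 (Fisher-z SE ≈ 1/√n against a ±0.02 band), closed-form AUC at
100,000/class (±0.005 band), coefficient recovery at 50,000/class
(within 2 SE), bootstrap coverage at 200 replications of n = 500 with
B = 300 (coverage is insensitive to B at this scale; the production
default stays B = 1000). The demo pipeline uses the cohort's 2,214/509
class sizes. Degenerate inputs fail loudly and early: single-class
outcomes, constant features, perfect separation, zero-width nomogram
ranges, non-PSD correlation matrices (rejected naming the offending
class), unwritable output paths.

## Known limitations

- The renderer controls only histogram-level statistics; it cannot test
  anything spatial.
- Backward elimination is one defensible selection path among several;
  on collinear real data it need not reproduce any particular published
  subset.
- The Hosmer–Lemeshow group count and the bootstrap CI style are
  conventions (g = 10, percentile); both are exposed as parameters.
- Probabilities exactly 0 or 1 are outside the Hosmer–Lemeshow domain
  and rejected; calibration curves accept them.
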