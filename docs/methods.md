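# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `sketchdev`, in the spirit of a package methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and rasterization

Drawings are ordered lists of strokes; a stroke is an ordered sequence of
`(x, y, t)` samples in canvas pixel units with non-decreasing millisecond
timestamps. The coordinate convention is raster-style throughout: origin
top-left, x rightward, y downward, 0-based indices. Stroke coordinates
are stored in source canvas units and scaled to the requested raster size
only at render time. Trials are capped at 30 s; longer recorded times are
clipped with a warning rather than dropped, since the capture software
enforces the cap.

Rasters are square grayscale arrays in [0, 1] with 1 = white. Rendering
draws strokes as connected polylines (round joints) in recorded order
with no anti-aliasing, so ink coverage is binary and
`ink_proportion` — the fraction of pixels strictly darker than white — is
exactly reproducible. The default raster is 224 × 224 at stroke width
3 px: 224 matches the standard input size of common convolutional
encoders, and 3 px keeps thin strokes visible after downscaling. The
source corpus format does not record a rendering resolution, so these are
package choices, exposed as parameters.

## Tracing registration

The tracing is registered to the target by maximizing normalized
cross-correlation (Pearson r over pixels). The printed form of this loss
in the source literature has an ambiguous normalization; we implement the
standard mean-centered, variance-normalized NCC, which is what
"pixel-wise correlation distance" names.

The transform family is translation ∘ rotation ∘ anisotropic scale about
the raster center, with no shear — exactly the components the error
decomposition needs, which also makes the decomposition unique. Rotation
is restricted to ±45°: tracings are not expected to be turned further,
and the bound keeps the rotation component identified for
4-fold-symmetric targets (a square rotated −30° or +60° is the same
image; without the bound the optimizer may legitimately return either).

Optimization is deterministic two-level Powell descent: a half-resolution
pass from three rotation starts (0°, ±20°) followed by a full-resolution
refinement of the best candidate, with parameters (tx, ty, θ, log sx,
log sy) bounded (|t| ≤ 0.35·size, |log s| ≤ log 2.5). The objective
smooths the *warped* tracing and the target with the same σ = 2 px
Gaussian. Smoothing before warping would scale the kernel along with the
image and bias the scale estimate — this ordering matters and is covered
by the recovery tests.

The reported shape error `1 − NCC` is evaluated at a heavier smoothing
(σ = 4 px) than the optimization uses. Scaling a rasterized tracing down
and back up loses sub-pixel detail; at σ = 4 that resampling blur
contributes ≲ 10⁻³ to the correlation distance, so the shape error
reflects contour mismatch rather than interpolation artifacts. On the
noise-free recovery grid (|t| ≤ 20 px, |θ| ≤ 30°, s ∈ [0.7, 1.4], at
160 px working resolution with the shape at 60% extent so every transform
stays in frame), parameters are recovered within 0.5 px / 1° / 2% and the
shape error stays below 0.01 — `tests/test_acceptance.py` runs exactly
this grid.

Error magnitudes: translation in pixels of the working resolution,
rotation |θ| in radians, scaling |log sx| + |log sy| (symmetric in
expansion vs shrinkage). Whether the original analyses used pixel or
normalized units is not recoverable from the source; the choice rescales
calibration coefficients but not rank order, which is what the tests pin.

## Ordinal calibration and tracing scores

Human 1–5 quality ratings are modeled as proportional odds:
`P(rating ≤ k) = σ(α_k − (xβ + u_rater))` with strictly increasing
thresholds (parameterized as a base plus log-increments) and per-rater
intercepts. No mixed-effects ordinal fitter exists in the Python stack,
so the rater intercepts are ridge-penalized with penalty 1/σ̂ᵤ², and σᵤ²
is estimated by an EM-style update `mean(û² + posterior variance)` using
the per-intercept curvature of the penalized objective (Laplace
approximation), iterated to a fixed point. Coefficient standard errors
come from the observed information (finite differences of the analytic
gradient). The fit is cross-checked in the tests against statsmodels'
`OrderedModel` in the no-rater-effect case.

One subtlety the tests document: duplicating every rating row is *not*
exactly neutral under the penalized fit (per-rater shrinkage depends on
per-rater counts); it is exactly neutral in the unpenalized
maximum-likelihood limit, and both facts are asserted.

A tracing's score is the latent-scale linear predictor xβ (rater effects
excluded): monotone in predicted quality, unbounded, and therefore usable
as a covariate in the production model. Session scores average the
session's tracings; sessions without tracings get no score rather than
zero.

## Recognizability

Embeddings are channel-normalized: convolutional maps are spatially
averaged per channel first, then every column is z-scored across the
corpus; zero-variance columns are dropped with a warning. Classification
is balanced K-way multinomial logistic regression with L2 penalty
C = 0.1: an equal number of drawings per category is subsampled
(seed-controlled, without replacement), split into disjoint folds holding
out 2 per category by default, and each drawing is scored by a model that
never saw it. Folds are disjoint partitions; whether the original
analyses used partitions or repeated random splits is not stated, so the
simpler deterministic reading is implemented.

The optimizer convergence tolerance defaults to 1e-4 rather than the
looser historical value sometimes quoted alongside C = 0.1: with ~50
classes the initial gradient of the multinomial loss is small enough that
a loose tolerance makes lbfgs accept the zero-coefficient start, silently
producing a chance-level classifier. Both hyperparameters are exposed.

Evidence is `ln(p/(1 − p))` with p clipped to [1e-12, 1 − 1e-12].
Zero-shot classification scores cosine similarity between image and label
embeddings; only the argmax is behaviorally meaningful, but a softmax at
temperature 100 is applied so evidence is defined for this classifier
too. Ties break toward the lowest label index and are flagged.

## Semantic confusions

For each misclassified drawing the top predicted category (the argmax,
necessarily ≠ target) either matches the target's attribute
(animacy; size for inanimate targets) or not. Matches are averaged per
(age, category) and corrected by the baseline prevalence of the target's
attribute class. The baseline is computed over the K − 1 non-target
*categories* by default — the candidate set of a confusion is categories,
not drawings — with a drawing-weighted mode available, since the source
wording admits both readings. Size is undefined for animals; such
drawings are skipped and tallied. CIs are percentile bootstraps
resampling categories.

## Part metrics

Consensus requires the identical label *set* from at least 2 raters (the
stricter reading of "same part label(s)"; a per-label majority mode is
provided). Strokes with fewer than 2 raters leave the agreement
denominator with a warning. Unique parts count distinct consensus labels
excluding unintelligible strokes; out-of-vocabulary (custom) labels can
be excluded by passing the vocabulary. Emphasis divides each consensus
stroke's Euclidean arc length (canvas units — resolution independent)
equally among its labels and normalizes by the total length of *all*
strokes, so emphases plus the unattributed fraction sum to 1 exactly.

## Recognition games

Exclusions run in a fixed order matching the data-collection narrative:
interference sessions; recognizers under 3 and adults; participants with
≤1 post-practice trial; trials with RT < 100 ms or > 10 s; participants
below 75% accuracy on photograph (practice + catch pooled) trials —
exactly 75% is retained. The report reconciles counts exactly and is
asserted to. "Don't-know" responses are retained and scored incorrect;
the source is not explicit on this, and the choice is documented here
rather than configurable.

Per-game evidence uses leave-one-out 4-way logistic models with the same
hyperparameters as the main classifier; categories with a single drawing
cannot be held out meaningfully and are skipped with a warning.

## Mixed-effects models

The three model contracts are: logit GLMM of per-drawing classification
(age, practice frequency, age × frequency, tracing score, draw time, ink,
stroke count; random intercepts for participant and category); the same
design with identity link on evidence, restricted to correctly classified
drawings; and logit GLMM of 4AFC accuracy on evidence × recognizer age
with random intercepts for subject and category plus random evidence
slopes by category. Predictors are z-scored by default (an 0–1 min-max
option exists, as the source describes both at different points; the
z-scored reading matches the reported standardized coefficients). No
multiple-comparison adjustment is applied.

Fitting backends: `lme4` (and `lmerTest`, giving Satterthwaite p-values
for linear models) via `Rscript` is the default when available;
statsmodels `MixedLM` (REML; normal-approximation p-values with a
warning) and variational-Bayes `BinomialBayesMixedGLM` are the
pure-Python fallbacks. The VB posterior SDs understate fixed-effect
uncertainty for logistic mixed models — in replicate simulations at the
sizes used here the empirical estimator spread was roughly 1.5× the VB
SD — which is why the lme4 path is preferred and the fallback warns.

The production–recognition correlation ranks each category's presented
drawings by classifier evidence (ties by drawing id), keeps the top 30%,
averages child accuracy per category, and correlates with per-category
production scores (Pearson, Fisher-z CI).

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical structure* the analyses assume,
not the visual appearance of child art:

- **Age grading.** Per-part inclusion probability rises linearly with age
  (0.35 at age 2, +0.07/year, clipped to [0, 1]); contour jitter falls
  linearly (9 px at age 2, −1.1 px/year, floor 1.5 px on a 300-unit
  canvas). These functional forms are package choices — the source
  provides no quantitative motor-noise model — and are surfaced as
  `AgeModel` parameters. They make mean unique parts, evidence, and
  recognition accuracy non-decreasing in age by construction, which is
  what the trend tests verify.
- **Class structure.** The default library mirrors the study scale: 48
  categories, 22 animate / 26 inanimate, half of the inanimate flagged
  big; a 16-category half-animate subset serves the part and recognition
  fixtures. Categories within a broad class share part vocabulary and
  embedding-prototype variance (`within_class = 0.5`), so confusions
  concentrate within class — without that structure the animacy/size
  decoding analyses would be vacuous.
- **Encoder.** `ToyEncoder` interpolates between pure noise (signal 0)
  and a deterministic prototype-plus-parts embedding (signal 1). It
  stands in for a pretrained deep encoder behind the same interface; real
  encoders can be plugged in, and nothing in the tests requires their
  weights.
- **Recognition.** Choice probability is a softmax with target utility
  β(age)·evidence, β rising linearly with recognizer age (0.8 at age 3,
  +0.25/year); photograph trials have a flat 5% error rate; RTs are
  lognormal with a configurable out-of-range fraction.
- **Ratings.** Generated from the same proportional-odds family the
  calibration fits, with rater intercepts of known SD — so calibration
  recovery is a genuine parameter-recovery test.

Passing tests on these data show the *machinery* is correct and
calibrated; they cannot show that real children's drawings satisfy the
generative assumptions, and coefficient magnitudes on real data depend on
the encoder used.

All generators are pure functions of (parameters, seed); one global seed
fans out to per-component streams by hashing a string label with CRC-32
into `numpy.random.SeedSequence`.

## Problem sizes

Default suite and acceptance-script sizes, chosen to exercise each
property at meaningful precision: 60-case registration grid at 160 px;
1500 ratings (500 tracings × 3) for calibration recovery; 576 drawings
for 48-way chance calibration and 3200 (16 × 200) per signal level for
evidence monotonicity; 960 misclassified drawings for attribute decoding
with B = 1000 bootstraps; 4000 drawings (200 participants, 16 categories)
for production-model recovery, 4500 trials (150 recognizers) for the
recognition model, and 200 replicates at n = 300 for the Type-I
calibration of the linear mixed model.

## Known limitations

- Registration assumes rotations under 45° and scale within ×2.5; a
  tracing drawn upside-down registers to a local optimum.
- The ridge approximation to rater random intercepts slightly
  underestimates the intercept variance when raters are few; coefficient
  SEs are observed-information and behave well in recovery tests.
- The VB fallback for logistic GLMMs should be treated as exploratory;
  conclusions about borderline effects need the lme4 backend.
- Anisotropic affines do not form a group (rotation and unequal scaling
  do not commute), so `AffineParams.inverse()` is defined only for
  isotropic scale; ground-truth grids use isotropic perturbations.
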