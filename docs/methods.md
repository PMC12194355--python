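# Methods

## Counting model and dose-reduction protocol

Planar scintigraphy pixels record photon counts, modelled as independent
Poisson draws: a pixel with expected full-acquisition count `a` acquired
for a fraction `f` of the standard time is `Poisson(f·a)`. The simulator
represents each synthetic subject by an *activity map* — a smooth,
nonnegative field of expected counts per pixel at full acquisition — and
realizes the dose-reduction protocol at the fractions 0.3, 0.4, …, 1.0.

Low-dose images are produced by **binomial thinning** of the full-dose
count image (each recorded photon kept independently with probability
`f`), not by an independent Poisson re-draw. Thinning a Poisson image is
marginally Poisson with the correctly scaled mean, but in addition shares
the realized anatomy and noise with its parent — the count-level analogue
of imaging the same patient in the same session for a shorter time, which
is the pairing the supervised objective assumes. An independent re-draw
mode exists behind a flag for sensitivity checks. Thinning guarantees
low ≤ full pixelwise; composition of thinnings with probabilities `p`
then `q` is statistically identical to one thinning with `p·q` (verified
to Monte-Carlo precision in the tests).

A point-source check mirrors the protocol's physical validation: a
Gaussian-blurred point kernel (σ = 2 px, a generic collimator blur; the
real detector response is not modelled) scaled to a target total count is
acquired at every protocol fraction, and the observed totals are fitted
against fraction by least squares through the origin. Slope ≈ total mean
counts and R² > 0.999 confirm count/dose-fraction linearity.

## Phantom anatomy

Anatomy is procedural — parametric ellipses, arcs and bands — because the
package may not ship or fetch atlas data. The thorax template is a
vertical spine column with periodic vertebral modulation plus lateral rib
arcs; the pelvis template is two iliac-wing annuli, a sacral wedge and an
optional bladder hot spot. Per-subject jitter (positions, axis lengths,
rib/vertebra counts) derives from the subject seed; templates are
smoothed (Gaussian, σ = 1.2 px) so the map is noise-free by construction.
Soft tissue emits at `background_rate` (default 10 counts/pixel per full
acquisition), bone at `background_rate × bone_rate_scale` (default ×5);
focal lesions add Gaussian-profile hot spots with peak
`intensity × background_rate`. The defaults put full-dose bone pixels
near 50 counts (≈14% relative noise) and 30%-dose bone pixels near
15 counts (≈26% noise) — a regime in which the noisy input's SSIM against
the full-dose reference spans roughly 0.65–0.97 across the protocol
fractions, wide enough to expose a denoiser's benefit and its high-dose
ceiling. No clinical count levels were available to calibrate against, so
these are stated defaults, not fitted quantities; attenuation, scatter,
septal penetration and tracer kinetics are deliberately out of scope.

Images are written as 8-bit grayscale PNG with a per-pair shared count
scale (the full-dose maximum), recorded in the manifest. Because a
shorter acquisition collects proportionally fewer counts, the stored
low-dose member of a pair is dimmer by roughly its dose fraction; pair
building therefore applies per-image max normalization by default,
emulating the standard clinical intensity normalization that removes
administered-activity variability from the model input. A `stored` mode
keeps raw intensities for experiments on the unnormalized pairing.

## Model

The denoiser is a fully convolutional autoencoder operating on [0, 1]
grayscale images whose sides are divisible by 2^(number of stages).

* **Encoder stage** (per width *w* in `encoder_widths`): multi-scale
  feature block — parallel 3×3 and 5×5 convolutions each producing *w*/2
  channels, channel concatenation, 1×1 fusion to *w*, GroupNorm, ReLU;
  then channel attention — global average pooling, FC to *w*/r, ReLU, FC
  to *w*, sigmoid, per-channel gating (r = `attention_reduction`); then a
  stride-2 3×3 convolution (GroupNorm, ReLU) halving both spatial dims.
  Kernels larger than 5×5 are excluded to avoid oversmoothing fine
  skeletal structure.
* **Bottleneck**: 1×1 convolution halving the channel count, ReLU.
* **Decoder stage**: transposed convolution with kernel 4, stride 2,
  padding 1 (exact spatial doubling; kernel divisible by stride avoids
  checkerboard artifacts), GroupNorm, ReLU, followed by `erb_per_stage`
  efficient residual blocks (depthwise 3×3 + pointwise 1×1 + GroupNorm +
  ReLU inside an identity skip). Decoder widths mirror the encoder at
  half width, continuing the bottleneck's channel budget.
* **Output**: 3×3 convolution to one channel; sigmoid maps to [0, 1]
  (a hard-clamp mode is available — the sigmoid is the default because
  the metrics assume the [0, 1] range and the clamp has zero gradient
  when saturated).

GroupNorm (default 8 groups) follows every learned convolution except the
final output convolution; exact placement is a design choice of this
package. Weights use seeded Kaiming-uniform fan-in initialization; biases
and GroupNorm offsets start at zero, gains at one. Parameter count is a
pure function of the configuration. Default widths are (32, 64) with two
downsampling stages.

All layers and their gradients are implemented on a compact numpy
reverse-mode autodiff core (`scintidenoise.nn`): tensors record parent
nodes and vector-Jacobian closures; convolutions use an im2col/einsum
forward with hand-written VJPs (the input gradient is one einsum over all
kernel offsets followed by a strided scatter-add); GroupNorm, attention
and the SSIM loss are composed from differentiable primitives. Every
primitive is finite-difference-checked in the test suite, and the
transposed convolution satisfies the conv/conv-transpose adjoint identity
to machine precision.

## Loss, optimization, early stopping

The objective is `λ·MSE + (1−λ)·(1 − SSIM)` with λ = 0.7, computed on the
normalized scale (data range 1). The SSIM inside the loss and the SSIM
reported by the evaluation module are the same formulation — Gaussian
window of 11 taps with σ = 1.5, K1 = 0.01, K2 = 0.03, moment (not
sample-corrected) covariances, mean taken over the region where the
window support is complete — so the two agree to ~1e-13 and the loss
decomposition `total = λ·mse + (1−λ)·(1−ssim)` is exact.

Optimization is Adam with learning rate 10⁻³ and standard moments
(β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸; unstated upstream, standard defaults
adopted). Batches of 16 are drawn per epoch with the remainder
(`n mod 16`) randomly excluded under a per-epoch derived seed and logged;
an epoch's exclusions are re-drawn the next epoch. "Iteration" means one
mini-batch update. The validation loss is measured before the first
update (baseline) and every `validate_every` iterations; patience counts
*validation evaluations* without strict improvement (with
`validate_every = 1` this coincides with counting iterations, satisfying
both common readings of patience-in-steps). Training returns the
best-validation parameter snapshot, not the last — consistent with
halting on validation non-improvement. Two runs with identical seeds
produce identical histories.

## Evaluation and statistics

Per test pair, PSNR and SSIM are computed for (low vs full) and
(denoised-low vs full) on the stored 8-bit scale (I_max = 255, honoring
the 8-bit PSNR convention); the loss-side preset uses data range 1.
Identical images yield an infinite PSNR sentinel, excluded from means
with a warning and masked out of the paired tests. Records are grouped by
dose fraction into a summary table (one row per fraction, ascending) with
group means and paired two-sided t-tests comparing original vs denoised
per metric; a zero-variance group reports a not-computable marker rather
than raising. Paired (rather than independent) tests are used because
both metrics are computed on the same pairs; no multiple-testing
correction is applied across the seven dose levels. TOST equivalence runs
two one-sided paired t-tests against ∓δ (default δ = 1, the ±1 band on a
five-point Likert scale) and reports the larger one-sided p.

The dataset split is 75/15/10 with subject-level grouping by default
(all pairs of a subject share a split), preventing anatomy leakage
between train and test; a per-image mode reproduces the stricter reading
in which individual pairs are assigned independently. Splits are not
stratified by dose fraction or region.

## Scaled study conditions

The packaged end-to-end study (`run_scaled_study`, also driven by
`scripts/acceptance.py`) runs at desk scale on one CPU: 40 subjects ×
2 regions × 2 views × 7 low-dose fractions (1120 pairs) at 64×64, batch
16, λ = 0.7, learning rate 10⁻³, 500 iterations with validation every 10
and patience 50. The model uses a single downsampling stage of width 16
(GroupNorm groups 4, attention reduction 4): with images four times
smaller linearly than a clinical 256×256 matrix, one stride-2 stage keeps
the latent-to-image compression comparable to two stages at full
resolution; a two-stage model at this image size compresses the latent
too aggressively to train well in a few hundred iterations. All phase
seeds derive from the single study seed (simulate: s, split: s+1,
training: s+2, initialization: s+3).

What passing the scaled study shows — and what it does not: the synthetic
phantoms reproduce the counting statistics, the pairing structure and the
dose-fraction geometry of the protocol, so the study demonstrates that
the implementation learns a genuine noise-level-adaptive denoiser
(largest gains at 30–50% dose, parity near 90%). It does not demonstrate
clinical performance: procedural anatomy lacks real anatomical
variability, pathology, attenuation and scatter, and the count levels are
assumed rather than calibrated, so the absolute SSIM/PSNR values are not
comparable to clinical tables.

## Numerical choices and degenerate inputs

* SSIM windows smaller than the image are required; an image smaller than
  11×11 raises a domain error suggesting a smaller window.
* Identical images: SSIM evaluates to exactly 1, PSNR to the +inf
  sentinel; the hybrid loss of a pair with itself is 0 up to the SSIM
  stability constants (< 1e-9).
* GroupNorm uses ε = 10⁻⁵; an all-zero pre-normalization block stays
  exactly zero (zero-weight blocks are identities where a skip exists).
* Thinning with `p = 1` returns the parent counts unchanged; `p ≤ 0` and
  `p > 1` are domain errors.
* Split apportionment uses largest-remainder rounding, so 100 pairs at
  75/15/10 give exactly (75, 15, 10) without grouping; with grouping the
  subject granularity dominates rounding.
* Checkpoints serialize the configuration, all weight blobs, seeds and a
  version field; loading reconstructs a bit-identical forward pass.

## Known limitations

* No attenuation, scatter or tracer-kinetics modelling; planar static
  views only — the simulator validates the algorithmic pipeline, not
  clinical image formation.
* The numpy training core is single-threaded-friendly but slow compared
  to GPU frameworks; the default 256×256/width-(32,64) configuration is
  trainable but intended for small studies.
* Human-observer machinery (Likert capture, inter-observer reliability,
  forced-choice preference collection) is out of scope; only the numeric
  paired-sample statistics those studies would feed are implemented.
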