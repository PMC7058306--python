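# Methods

This note documents the models, parameters and design choices behind
`cytogan`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic data can and cannot show.

## Synthetic cytology generator (`synthcyto`)

Each patch is a light slide background (RGB ≈ (232, 229, 234), ±5%
brightness jitter) carrying a clump of cells. Cells are overlapping ellipses:
a cytoplasm ellipse tinted with the class palette, and an interior nucleus
ellipse whose pixels get Gaussian "chromatin" speckle. Cell centers are drawn
around a clump center with an isotropic Gaussian of scale `clump_spread`.
A single global Gaussian blur with σ drawn from `focus_blur_sd_range`
emulates manual-focus variation. All draws come from one
`numpy.random.Generator` per patch, so a (parameters, size, seed) triple maps
to bit-identical pixels.

Class separation encodes the morphologic atypia cues a cytologist reads —
nuclear size, nucleus-to-cytoplasm (N:C) area ratio, chromatin coarseness:

| parameter | benign | malignant | units |
|---|---|---|---|
| nucleus radius | 0.030–0.045 | 0.060–0.090 | fraction of patch size |
| N:C area ratio | 0.25–0.40 | 0.55–0.80 | — |
| chromatin speckle SD | 10 | 28 | 8-bit intensity |
| cells per patch | 4–9 | 4–9 | — |
| focus blur σ | 0.002–0.008 | same | fraction of patch size |

Radii scale with patch size so a 32×32 desk-scale patch carries the same
relative class signal as a 256×256 one. The dark-pixel fraction (mean channel
< 128) acts as a nuclear-area proxy and separates the classes by more than
one pooled standard deviation; a logistic regression on (mean intensity,
dark-pixel fraction) classifies held-out patches essentially perfectly. The
generator does **not** model real staining chemistry, three-dimensional
clump thickness, nucleoli, inflammatory background, or specific carcinoma
subtypes; a test passing on these images demonstrates that the pipeline's
mechanics work, not that clinical accuracy would be reproduced.

Synthetic "cases" group `patches_per_case = 5` consecutive patches so
case-grouped cross-validation is meaningful.

## Patch preparation (`patchprep`)

Tiling uses 0-based, top-left-origin, row-major coordinates; a W×H field at
patch size P yields exactly ⌊W/P⌋·⌊H/P⌋ patches, and leftover right/bottom
margins are discarded rather than padded (patches are exact and
non-overlapping). Benign-case patches inherit the case label; malignant-case
patches require a per-patch review entry, and a missing entry raises rather
than defaulting — expert review is a hard precondition, not a heuristic.
Excluded patches remain in the manifest with `label = excluded` for
auditability.

## Augmentation (`augment`)

The family is the Cartesian product of rotations {0°, 90°, 180°, 270°},
flips {none, horizontal}, per-channel RGB gain triples (identity always
present; defaults add ±10% single-channel and global variants), and filters
{identity, Gaussian blur, edge enhancement}. The vertical flip is omitted
because it equals horizontal flip ∘ 180° rotation and would duplicate group
elements. "Color correction" is gain jitter standing in for
staining-intensity variation. Filter defaults: Gaussian σ = 1.5 px; edge
enhancement is the unsharp mask I + a·(I − G_σ I) with a = 1.0. Expansion to
the per-class target draws without replacement from the non-identity variant
pool with the config seed, maximizing diversity and guaranteeing no repeated
(origin, transform) pair; every original appears exactly once untransformed.
Augmentation belongs to training partitions only — evaluation patches are
never augmented.

## Progressive GAN (`gan`)

One GAN per class. The generator maps a 128-value standard-normal latent to
a 4×4 image through a dense layer plus 3×3 convolution, then each stage
appends {nearest-neighbor ×2 upsample, two 3×3 convolutions}; per-stage
1×1 to-RGB layers and a tanh bound the output in [−1, 1]. The discriminator
mirrors this with from-RGB layers, downsampling blocks and a
minibatch-standard-deviation feature at 4×4. During growth the new block
fades in linearly: output = α·new + (1−α)·upsampled-old, α = min(step /
fade_steps, 1), with `fadein_fraction = 0.5` of each stage's steps spent
blending. Stabilizers from the progressive-growing recipe — pixel-wise
feature normalization in the generator, the minibatch-std layer, equalized
learning rate — are on by default and individually switchable for ablation.

Training is the Wasserstein formulation: critic loss mean(fake) − mean(real),
generator loss −mean(fake), Adam (lr 0.001, β₁ = 0, β₂ = 0.999), 100 epochs
per scaling step at full scale. The critic's Lipschitz constraint is enforced
by weight clipping. Because parameters live in the equalized-learning-rate
parametrization (unit-variance weights rescaled by the He constant at run
time), the clip threshold defaults to 1.0 — the analogue of the classic 0.01
for raw weights; clipping raw-scale weights at 0.01 would zero out the
rescaled critic. A gradient-penalty variant of the loss formula is exposed
(`wasserstein_losses` accepts a penalty term, and the critic's input-gradient
norm can be logged as a diagnostic), but parameter updates use clipping:
exact penalty optimization needs second-order backpropagation, which the
numpy framework deliberately does not implement.

Real images are average-pooled to each stage's resolution. The sliced
Wasserstein distance — the mean 1-D Wasserstein-1 distance over 64 random
unit projections of flattened patches — is the quality metric, reported per
stage; it is a pseudometric (non-negative, symmetric, zero on identical
sets) and reduces to mean |sorted(a) − sorted(b)| in 1-D. The
Laplacian-pyramid SWD variant is out of scope. After 2 stages (100
epochs/stage) on 64 synthetic patches, SWD(real, generated) is roughly a
third of SWD(real, uniform noise).

The DCGAN baseline generates the full resolution directly from the latent
(5 convolutions, 4 upscaling layers; discriminator 6 convolutions + 1 output
layer) and trains with the standard non-saturating GAN loss, Adam lr 2×10⁻⁵,
β₁ = 0.5, minibatch 32.

## Two-step classifier (`classifier`)

The backbone is VGG-16 (13 convolutions in 2-2-3-3-3 blocks) or `vgg_tiny`
(1-2-2 blocks at ≤64 channels, 32×32 input), with the original FC layers
replaced by a 1024–256–2 head; the two outputs pass through a softmax, and
the malignant probability is the score (ties at the 0.5 cut-off classify as
malignant, favoring sensitivity in a screening setting). Loss is
cross-entropy — the only choice consistent with a two-unit probabilistic
output. Reference optimizer settings, identical across both steps: Adam,
lr 10⁻⁶, β₁ = 0.9, β₂ = 0.999, minibatch 32 (`TwoStepPlan.reference()`).
Desk-scale runs use lr 10⁻³ and tens of epochs, since 10⁻⁶ is an
end-of-fine-tuning rate appropriate to a full-size pretrained network, not
to a small randomly initialized one; epoch counts are config values.

Pretraining updates every parameter on GAN-labeled GAN images; fine-tuning
rebuilds the optimizer over head parameters only and stops backpropagation
at the head, so convolutional weights are bitwise identical before and
after — an exactly testable freeze contract. The ImageNet arm loads conv
weights from a user-supplied `.npz` checkpoint when given; offline it falls
back to random initialization and records `init_used = "random_fallback"`,
and reports label the arm accordingly (the head is still the only trainable
part, preserving the fine-tune-only protocol).

## Evaluation (`evalstats`)

Benign is negative, malignant positive. Prediction records pool across folds
into a single confusion matrix before metrics are computed (one matrix for
the whole evaluation pool, rather than averaged per-fold metrics). ROC curves
sweep the cut-off over distinct scores with ties grouped into single steps;
the trapezoidal AUC then equals the Mann–Whitney statistic with ties counted
½, which the tests verify against a brute-force pairwise oracle. Metrics are
full precision internally and rounded to 3 decimals only in reports; an empty
class row raises rather than returning NaN.

The split planner holds out a fixed-size validation set (default 173
patches), sampled stratified by label at patch level (largest-remainder
apportionment between classes), then partitions the remaining pool into
three stratified folds — grouped by case by default so no patient spans two
folds, with patch-level grouping available. The holdout is patch-level even
under case grouping because an exact-count case-wise holdout is generally
unattainable; leakage control matters between training and test folds, which
case grouping covers.

## Desk-scale experiment (`pipeline`)

`ScaledExperimentConfig` defines the problem sizes used by the tests and the
acceptance script, chosen to exercise every stage faithfully on one CPU:
32×32 patches, 90–120 per class, a 2-stage progressive schedule (4→8, 32
feature maps, 12 epochs/stage, minibatch 16), 150 GAN samples per class for
pretraining (nearest-upsampled to the classifier input), vgg_tiny, 8
pretraining and 15 fine-tuning epochs at lr 10⁻³. The three arms are
PGGAN-pretrained, DCGAN-pretrained (both fine-tune the head on real
patches), and the no-GAN baseline (head-only training; random-init fallback
standing in for ImageNet weights offline). With 90 per class and a third
held out, the fine-tuning set is small (60/class) — the regime the two-step
scheme targets — and over seeds 0–4 the GAN-pretrained arm averages 0.997
held-out accuracy vs 0.983 for the baseline.

## Known limitations

- The synthetic classes are far easier than clinical benign/malignant
  discrimination; absolute accuracies here say nothing about clinical
  performance, only directions and mechanics.
- Weight clipping is a blunter Lipschitz constraint than a gradient penalty;
  at desk scale it trains stably, but the penalty path would need an
  autodiff substrate.
- The ImageNet arm without a supplied checkpoint is a random-init head-only
  baseline, labeled as such; it is a lower bound on what true ImageNet
  features would provide.
- Full 256×256 progressive training with the 512-feature-map schedule is
  GPU-scale and not attempted; the full schedule is constructed and verified
  structurally.
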