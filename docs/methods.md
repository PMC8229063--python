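# Methods

## The model

DRE-Net is a two-stage classifier for post-operative shoulder radiographs.
Stage one extracts features with two convolutional backbones truncated at
their global average pooling:

* **modified ResNet-50** — 7×7/2 stem convolution, 3×3/2 max pool, four
  bottleneck stages of (3, 4, 6, 3) blocks, global average pool; output
  f₁ ∈ ℝ²⁰⁴⁸.  Stage outputs for a 224×224×3 input are 112×112×64,
  56×56×64, 56×56×256, 28×28×512, 14×14×1024, 7×7×2048, 1×1×2048.
* **modified DenseNet-201** — the same stem, four dense blocks of
  (6, 12, 48, 32) layers with growth rate 32 and halving transitions, a
  final batch norm, global average pool; output f₂ ∈ ℝ¹⁹²⁰.  Stage
  outputs are 56×56×256, 28×28×128, 28×28×512, 14×14×256, 14×14×1792,
  7×7×896, 7×7×1920, 1×1×1920.

Stage two, the shallow concatenation network (SCN), concatenates
f = [f₁ | f₂] ∈ ℝ³⁹⁶⁸ (residual features first — the order is
statistically irrelevant but frozen for reproducibility) and applies one
fully connected layer z = W f + b (W ∈ ℝ^{K×3968}, K = 4) followed by a
softmax.  The softmax is computed with max-subtraction, which is exactly
equivalent and numerically stable; argmax ties break toward the lowest
class index.  The loss is cross entropy, CE = −log p_t.

Because no deep-learning framework is available in this environment, the
backbones run on a compact numpy CNN core written for this package
(`drenet.nn`): im2col convolutions, batch normalization, max/average
pooling and linear layers, each with an explicit backward pass verified
against central finite differences on down-scaled configurations.

## Rotational invariant augmentation

Training images are rotated in-plane about the geometric image centre
((H−1)/2, (W−1)/2) through 36 angles {0°, 10°, …, 350°}; the 0° copy is
one of the 36, so 538 training images become 19,368 and 377 become
13,572.  Rotation keeps the canvas size (content leaving the frame is
discarded, exposed corners take a constant fill, default black) and uses
bilinear interpolation except at multiples of 90°, which are exact array
re-indexings.  Test images are never augmented.  The interpolation and
corner conventions are not dictated by the protocol being reproduced;
these are the most common choices.

## Training

Both regimes use classical momentum SGD with the L2 term added to the
gradient:

    v ← momentum·v − lr·(∇L + l2·θ),    θ ← θ + v

with mini-batch 10, lr 0.001, momentum 0.9, l2 10⁻⁴.  Sequential
training fine-tunes each backbone for 13 epochs under a temporary
4-class softmax head (discarded afterwards), freezes them, extracts
concat features once, and trains the SCN for 9 epochs; end-to-end
training updates everything jointly for 7 epochs.  A learning-rate drop
factor of 0.1 is recorded in the configuration but no drop period is
defined by the source protocol, so the default schedule is constant.  A
stratified 25% validation split is carved from the training samples for
monitoring only; there is no early stopping.

Two numerical safeguards matter when the extractors start from random
weights rather than transfer-learned ones:

* **SCN input conditioning.**  The SCN trainer standardizes each feature
  on the training portion and folds the affine map back into the
  returned head, so the fitted classifier is still a single linear layer
  on raw features.  Unnormalized random-extractor features have per-
  dimension scales near 40 (the residual trunk has no output
  normalization), and momentum SGD at lr 0.001 diverges on them.
* **Gradient clipping.**  The batch trainers cap the global gradient
  norm at 10 (configurable, disableable).  With small mini-batches the
  batch-norm statistics of a random-initialized deep stack can produce
  step-one gradients of order 10²–10³, which otherwise send the
  parameters to overflow within a few steps.  The bare `sgd_step`
  operation implements the unclipped rule.
* **Batch-norm calibration.**  `calibrate_batchnorm` replaces the (0, 1)
  initialization of the running statistics with statistics observed on a
  small image sample, after which inference is deterministic and
  batch-independent.  The evaluation runners apply it to frozen
  random-init extractors (16 images by default).

## Evaluation

**Closed world.**  Stratified k-fold (default k = 10): within each class
samples are shuffled by the run seed and dealt into folds whose sizes
differ by at most one, remainders to the earliest folds; for the real
class sizes 83/294/71/149 this reproduces the published per-fold test
bands ({8,9}, {29,30}, {7,8}, {14,15}) and a 538-image training portion
for a 59-image test fold.  Per fold, RIA is applied to the training
portion only; metrics are averaged over folds.

From the confusion matrix (rows true, columns predicted) the per-class
one-vs-rest counts give macro precision = mean TP/(TP+FP) and macro
recall = mean TP/(TP+FN); F1 = 2PR/(P+R) from the macro means; accuracy
defaults to overall (trace/total).  Two literal modes are kept for
auditability of the printed formulas they mirror: `eq4_literal` accuracy
(macro mean of one-vs-rest binary accuracies; for K classes it equals
100 − 2(100 − overall)/K) and `eq7_literal` recall (TP/(TP+TN), which is
not a recall — the printed denominator is almost certainly a typo, so the
standard form is the default).  Zero denominators contribute 0 with a
warning.  Method comparison uses a two-tailed paired t-test over the
4 metrics × k folds pooled values; all-zero differences give p = 1 and
constant nonzero differences give p = 0 (reported as below machine
epsilon).

**Open world.**  Train and test class sets are disjoint (default runs:
train {C1,C2} test {C3,C4} and the three other pairings).  Queries are
identified by the smallest Euclidean distance between their concat-layer
feature (head weights unused) and per-class mean vectors.  Reference
means are computed from unaugmented images, and the mean of a query's own
class is leave-one-out, so no query ever contributes to its own
reference — the most conservative reading, since the source protocol does
not say whether the query was included.  New classes register by storing
a mean vector and label; nothing is retrained.

**PCA + KNN ablation.**  Concat features are centred and decomposed by
SVD (eigenvalues s²/(N−1); eigenvector signs fixed by forcing the first
nonzero coordinate positive).  The retained eigenvector count λ is chosen
by seeded k-fold cross-validated accuracy on the training features only,
ties to the smallest λ; the classifier is brute-force KNN with K = 1 by
default (K is not specified by the source protocol; 1 is the smallest
assumption) and all ties break toward the lowest label.

## The synthetic generator

Real post-operative radiographs show a bright metallic prosthesis — a
rod-like humeral stem topped by a head component — over soft tissue.  The
generator renders that structure deterministically: per class, stem
length/width and head radius are drawn from closed integer ranges, the
head is a full disc (C1, with collar), a hemisphere (C2 and C4) or an
angled wedge (C3), the silhouette is drawn at 4× oversampling, rotated by
a pose angle (±25°), translated (±10 px), composited over a vertical
intensity gradient (soft tissue) and degraded with clipped Gaussian noise
(σ ≈ 5–11).  In easy mode every geometric range is disjoint across
classes; hard mode pulls C4's stem and head into C2's ranges to emulate
the confusable Depuy/Zimmer pair.  Per-sample seeds are SHA-256 hashes of
(master seed, index), so regeneration is byte-identical and order-
independent.  An independent normalized cross-correlation template
matcher (tests/oracle_templates.py) classifies ≥95% of easy-mode phantoms
and verifiably degrades in hard mode.

What the generator does not emulate: real model-level intra-class
variability (16 implant models behind 4 labels), exposure and positioning
variation, bone texture, beam hardening, scatter, or annotations burned
into clinical films.  Passing the synthetic recovery study therefore
demonstrates that the pipeline's machinery — augmentation, feature
extraction, training, both evaluation protocols — is correctly wired and
can recover planted class structure; it says nothing about clinical
accuracy.

## Reduced-scale recovery study

`drenet.protocols.reduced_scale_study` runs the full pipeline at a size
one CPU handles: 120 easy-mode phantoms (30 per class) at 56×56 input,
frozen random-init extractors with batch-norm calibration, full 36-angle
RIA, two-fold closed-world cross-validation (≈60 train / 60 test per
fold) and the four open-world runs, with the SCN trained exactly per the
published recipe.  Concat features are cached per (image, angle) and
shared between the two configurations, which keeps one seed near three
minutes.  Batch-norm calibration uses 16 images spread over the whole
dataset rather than each fold's training portion — an unsupervised,
label-free normalization, but strictly a mild transduction; it lets the
feature cache be shared across folds, and it measured as
performance-neutral against train-only calibration.

Known limitation: without transfer-learned weights the extractors are
random projections, and their calibrated features carry less class
information than trained ones — the separability ceiling of the features
varies with the initialization seed, and the closed-world accuracy of the
reduced-scale study inherits that variation.  The open-world
nearest-class-mean identification is less sensitive to it.  The test
suite and `scripts/acceptance.py` report the measured values.
Reproducing the published ~86% on real data requires the real dataset
and pretrained backbones, which this package deliberately does not
download.
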