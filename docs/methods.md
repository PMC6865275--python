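# Methods

## Problem and model

`gridattn` classifies high-resolution single-tissue histopathology
images into four esophageal classes — normal, Barrett esophagus (BE)
without dysplasia, BE with dysplasia, and adenocarcinoma — using only
tissue-level labels. Diagnostic lesions typically occupy a small part
of a large tissue, so the model must find them without being told where
they are.

A tissue of H × W pixels is tiled into an r × c grid of 492-px cells
(r = ⌈H/492⌉, c = ⌈W/492⌉, white padding at the edges so no tissue
pixel is lost), each cell resized to 224 px and standardized by the
per-channel mean/SD pooled over the training tissues. A shared CNN
backbone maps each cell to a k-vector, giving the grid feature map
U ∈ R^{r×c×k}. F learnable attention filters of size k × d × d
(d = 3, zero padding 0 in depth and 1 in height/width) score the grid:

    e_f = W_f ∗ U + b_f            (f = 1…F, e_f ∈ R^{r×c})
    α_f = softmax over the r·c positions of e_f
    z_f = Σ_{ij} α_f[i,j] · U[i,j,·]
    z   = concat(z_1, …, z_F),  dropout(p = 0.5),  linear → 4 logits

Because the kernel spans the full feature depth with no depth padding,
the "3-D" convolution reduces exactly to a 2-D convolution with k input
channels and F output channels, and is implemented that way. Softmax
normalization makes each α_f a nonnegative weight map summing to one,
so z_f is an affine (convex) combination of cell features; the choice
of softmax (over, say, sigmoid-then-normalize) gives well-behaved
gradients and satisfies the affine-combination constraint directly.
Nothing in the module depends on r or c: the same filters slide over
any grid, so tissues of any rectangular size pass through one model.

Training minimizes the softmax cross-entropy against the tissue label
only; gradients flow through α into the backbone, which is how the
attention discovers diagnostic regions without lesion annotations.
Predicted class is the argmax of the probabilities; exact ties resolve
to the lowest-risk class (deterministic and clinically conservative).

## Backbones and freeze policy

The backbone is pluggable behind one contract (normalized cell →
k-vector, weight-shared across cells, global-average-pooled):

* **TinyCNN** (default at desk scale): a parameter-free 8× average-pool
  stem followed by three conv–batchnorm–ReLU blocks, k = 16. It trains
  end to end on one CPU in minutes and is used in all shipped
  experiments.
* **ResNet-18 layout** (k = 512, classification layer removed) for
  paper-scale work; its eight residual blocks are exposed individually.
  Pretrained weights can be loaded from a checkpoint; none ship with
  the package.

The freeze policy disables gradients in the stem and every block except
the last, as a regularizer; batch normalization inside frozen blocks
runs in inference mode even during training, so frozen statistics
cannot drift. All network machinery (conv/batchnorm/pooling/linear
layers, dropout, Adam, manual backpropagation) is implemented in NumPy
inside `gridattn.nn`; forward passes and gradients are verified in the
test suite against scipy correlation oracles, nested-loop oracles and
central finite differences.

## Training recipe

Defaults (all in `TrainConfig`):

| parameter | default | note |
|---|---|---|
| optimizer | Adam (β, ε at library defaults) | |
| initial lr | 1e-3, ×0.95 per epoch | |
| cycle reset | lr = 1e-4 every 50 epochs | decay continues within each cycle (a config switch disables this, since either reading of the cyclical schedule is defensible) |
| epochs | 200 | desk-scale studies use 30 |
| batch size | 2 | assembled by per-image forward/backward with gradient accumulation, because grids vary in shape across tissues |
| augmentation | one random rotation + isotropic scale in [0.8, 1.2] | rotation defaults to multiples of 90° (no interpolation artifacts); a continuous mode exists |
| dropout | 0.5 on z | |
| initialization | MSRA for conv (variance 2/fan_in), Glorot for fully connected (variance 2/(fan_in+fan_out)), batch-norm scale 1 / shift 0 | |

Model selection keeps the checkpoint with the best validation accuracy
(training loss breaks the tie when no validation set exists). Channel
statistics come from the training tissues only. When augmentation is
off, the activations of the frozen backbone prefix are constant per
tissue; they are computed once and cached, which is a pure
optimization with no effect on results.

## Synthetic tissue generator

The generator emulates the study's data: single-tissue subimages cut
from 20× hematoxylin-eosin scans, four classes mixed 51.5 / 21.1 /
12.1 / 15.3% (195/80/46/58 of 379), tissues grouped 1–3 per pseudo-slide
so splits can keep same-slide tissues together. Two size regimes:
"paper" draws log-normal sizes matching the reported tissue dimensions
(width median 4500 px, IQR 3000–6500; height median 5500 px, IQR
4000–7500); "desk", the default, fixes 1476 × 1968 px — a 3 × 4 grid of
492-px cells — for CPU-scale runs.

A tissue is an ellipse of class-specific texture on near-white glass
(≥ 240 per channel, so background removal is exercised); lesions are
axis-aligned rectangles with Gaussian-blended edges, matching the
bounding-box granularity of clinical annotation, planted inside the
ellipse. Textures are band-limited Gaussian noise around
class-specific base colors with class-specific granularity (darker and
busier with increasing severity, a cartoon of hematoxylin uptake);
non-normal tissues carry 1–2 lesions of their class and occasionally
one lower-risk lesion, so the highest-risk labelling rule is active.
Everything is deterministic given the seed.

What this does and does not show: the textures are linearly separable
by color and variance statistics (a kNN on simple crop statistics
exceeds 80% accuracy by construction), so passing the end-to-end test
demonstrates that the architecture, gradients, training loop and
attention localization work — not that the model would reach clinical
accuracy on real histology, where classes differ by cellular
morphology rather than color, stain varies, and lesions are not
rectangles.

## Sliding-window baseline

The comparison method trains a 224-px crop classifier on box-derived
crops (crop centers inside the boxes; normal crops from lesion-free
tissue; color jitter, flips and rotations as augmentation; weight decay
1e-4 and a ×0.1 lr step at epoch 50 — the exact regularization values
are config-exposed choices, not claims about prior work), slides it
densely over each tissue, and aggregates: count windows whose class
probability exceeds that class's threshold, predict the highest-risk
class whose count reaches its minimum, else normal. The published
heuristics behind this family of systems are pathologist-derived and
unpublished in detail; this counting rule is a declared stand-in with
the same interface, tuned by exhaustive grid search on validation mean
F1 (ties prefer lower thresholds). The baseline raises a dedicated
error without box annotations — the contrast with the annotation-free
attention path is part of the design.

## Evaluation statistics

One-vs-rest accuracy, recall, precision, specificity and F1 per class,
plus an unweighted mean over the four classes (the convention under
which per-class accuracies 0.70/0.85/0.89/0.88 average to 0.83).
Zero-denominator metrics return 0 with an `undefined` flag rather than
NaN so mean rows stay computable. Confidence intervals are percentile
bootstrap over (label, prediction) pairs, B = 2000 by default
(B unstated in the statistical tradition this follows; 2000 makes the
95% endpoints stable to ~0.01). Paired classifiers are compared with
the two-tailed McNemar–Bowker symmetry test; degrees of freedom count
only the off-diagonal pairs with at least one disagreement (pairs never
observed carry no information), which coincides with the standard
K(K−1)/2 on dense tables — the implementation is cross-checked against
statsmodels there. ROC curves/AUCs are one-vs-rest on the predicted
class probability, delegated to scikit-learn.

Attention localization is quantified by the enrichment ratio: attention
mass inside the lesion's grid cells divided by the lesions' share of
cells, computed for the head with the largest classifier-weight mass
toward the adenocarcinoma logit (an explicit, testable proxy for "the
head optimized for adenocarcinoma features"). Grid-cell lesion masks
use a ≥ 50% cell-overlap rule. Uniform attention scores exactly 1; the
shipped study measures ≈ 7.

## Problem sizes of the shipped experiments

The end-to-end study (tests and `scripts/acceptance.py`) uses 200
training / 40 validation / 60 test desk-scale tissues, the TinyCNN
backbone (k = 16) with 8 attention heads, 30 epochs with augmentation
off, bootstrap B = 1000; the baseline trains 15 epochs on ~3 crops per
box. These sizes keep a full run in minutes on one CPU while leaving
the observed margins (accuracy ≈ 0.93 vs. the 0.90 gate; enrichment
≈ 7 vs. the 2.0 gate) wide.

## Numerical and degenerate-input choices

* Convolutions run as im2col matrix products in float32; attention
  softmax is max-subtracted for stability.
* A degenerate channel SD is floored at 1e-6 with a warning.
* An all-zero attention map renders as zeros with a warning (max
  normalization would otherwise divide by zero).
* Background test: a pixel is glass when all channels ≥ 240/255;
  connected components under 0.1% of the slide area are discarded as
  debris. Both are configurable; the thresholds are explicit choices,
  as the tradition this follows reports only "white background
  removed".
* Boxes are 0-based half-open; grids are row-major — one convention
  repo-wide.

## Known limitations

* The synthetic task is far easier than real histology (see above);
  no claim about clinical performance follows from it.
* The NumPy networks are CPU-bound and single-threaded beyond BLAS;
  paper-scale images with the ResNet-18 backbone are functional but
  slow, and no pretrained weights are bundled.
* Pyramidal slide formats (SVS/NDPI) are out of scope; inputs are
  PNG/TIFF rasters.
* Hard/stochastic attention and multi-scale variants are deliberately
  not implemented.
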