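# Methods

## Problem and scope

The package classifies single-cell crops of stained blood smears into the
four prevalent leukocyte classes (eosinophil, lymphocyte, monocyte,
neutrophil; fixed alphabetical index order). Basophils, below 1% prevalence,
are outside the class set and a `basophil` label is rejected rather than
silently dropped. The pipeline has four stages — preprocessing, HSV
threshold segmentation, dense-connectivity feature extraction, and
classification with a one-cycle-trained softmax head — each usable on its
own.

## Synthetic smear generator

Real single-cell smear collections are emulated by an analytic renderer:

* one cell per frame, centered with ±5% positional jitter, matching the
  single-cell crop dialect of public blood-cell datasets;
* cytoplasm: a filled, rotated ellipse (axis ratio 0.85) without
  anti-aliasing, so the ground-truth mask is exactly the rendered pixel set;
* nucleus: 1–3 overlapping ellipse lobes sized so their union approximates
  the class's nucleus-to-cell area fraction; the monocyte nucleus has a
  circular bite carved out to mimic its kidney shape;
* background: pale and desaturated (HSV ≈ (0.12, 0.08, 0.96)); all stain
  hues sit in the blue–magenta band [0.55, 0.92], away from the 0/1 hue seam;
* noise: additive uniform RGB noise of amplitude 0.02, chosen to stay well
  inside the margin between background saturation (~0.08) and the 0.45
  segmentation threshold;
* determinism: a sample is a pure function of (appearance, image_side,
  seed); dataset sample seeds are `master_seed + index`, class-major.

Class appearances differ in hue, nucleus lobe count, nucleus area fraction
and cell radius (eosinophil 70 px, lymphocyte 55 px, monocyte 90 px,
neutrophil 65 px at the 240 px reference frame; radii scale with the
rendered side). These differences make the four classes separable by a
nearest-centroid rule on (mean hue, mean saturation, foreground area) with
≥ 0.9 accuracy, which is what guarantees the training targets below are
achievable at desk scale.

**What passing tests show and do not show.** The generator captures the
color-contrast and gross-morphology cues a threshold segmenter and a small
CNN rely on. It does not model staining variability, illumination gradients,
touching/overlapping cells, debris, platelets or red-cell background
texture; perfect synthetic accuracy therefore demonstrates that the
machinery is correct, not that it would reach comparable numbers on real
smears.

## Preprocessing

Images are resized bilinearly to a square target side, default 244
(deliberately kept although the canonical dense-net input is 224;
configurable), with values clipped back into [0, 1]. Channel normalization
is `(x − μ_c)/σ_c`. Two deliberate choices:

* `normalize_train_only` (default on) applies normalization to training
  images only. With data-dependent statistics this creates a
  train/validation distribution shift, so the shipped default statistics are
  the identity (μ = 0, σ = 1), which keeps the rule benign;
  `compute_channel_stats()` provides per-dataset statistics for callers who
  opt in, and they should then normalize both subsets.
* Augmentation (flip/rotate/zoom) is available for synthetic data but off
  by default, because the reference datasets this dialect mirrors ship
  pre-augmented.

The stratified splitter draws a seed-deterministic permutation per class and
assigns `round((1 − fraction)·n)` items (banker's rounding) to validation —
always the floor or ceiling of the exact share. Published per-class
validation counts such as 623/620/620/624 are treated as printed constants
to be summed, not as recomputable outputs: no single rounding rule
reproduces them from an exact 80/20 split.

## HSV segmentation

Inequality directions, unstated in the classic threshold-mask recipe, are
fixed as: lower-hue mask keeps hue ≥ ℓ, upper-hue mask keeps hue ≤ u,
saturation mask keeps S ≥ s_min (removing the pale background and keeping
the stained cell). The "transparency" channel is read as saturation — HSV
has no alpha and the mask in question is the saturation mask. Hue bounds are
a plain interval; wraparound across the red seam is intentionally not
handled, and the generator keeps stain hues away from the seam. Morphology
is binary opening then closing with a disk of radius 2 (radius 0 = identity):
opening removes speckle, closing fills holes. Only the neutrophil thresholds
(0.0, 1.0, 0.45) are canonical; the other three class defaults were tuned
once on the synthetic generator and are documented as such. Whether
segmentation feeds the classifier is a configuration flag (`segmentation.enabled`,
default off — raw images flow to training); both wirings are supported.

## Dense-connectivity model

The connectivity contract is the contribution: inside a block, layer *l*
consumes the channel-wise concatenation of the block input and all previous
layer outputs (k₀_block + (l−1)·k channels), so an L-layer block has
L(L+1)/2 direct connections; residual networks, by contrast, merge input and
output by addition, which overwrites rather than preserves earlier features.
Layer internals follow the standard bottleneck recipe BN → ReLU → 1×1 conv
(4k) → BN → ReLU → 3×3 conv (k); transitions are BN → ReLU → 1×1 conv with
compression 0.5 → 2×2 average pooling; the stem is a 3×3 conv + BN/ReLU +
2×2 max pool; the head is global average pooling into a linear layer.
Head replacement re-initializes only the final linear map (zero bias,
σ = 0.01 Gaussian weights, seeded); the backbone is left bit-identical and
can be frozen. Freezing defaults to off: full fine-tuning is the default
because the transfer recipe is ambiguous between frozen and fine-tuned
descriptions, and a flag covers both.

The layers run on a hand-written numpy backend (im2col convolution, batch
normalization with running statistics, SGD with momentum 0.9 and L2 weight
decay 10⁻⁴), float32 activations, every backward pass verified against
central finite differences in the test suite. Loading externally trained
weights is possible through the checkpoint format (npz + JSON sidecar) but
no functionality depends on it.

## One-cycle schedule

`build_schedule` partitions a budget of T iterations into an ascent of
`s = ⌊T(1 − f)/2⌋` iterations (min → max, linear), a symmetric descent
(max → min), and an annihilation tail of the remaining iterations
(min → final, linear), with defaults f = 0.1 and final = min/100 — "much
further below the minimum" made concrete. The schedule is continuous and
symmetric about its peak.

The range test increases the rate linearly (log spacing optional), smooths
losses exponentially (coefficient 0.98, bias-corrected), stops once the
smoothed loss exceeds 4× the best smoothed loss or goes non-finite, and
suggests the rate at the smoothed-loss minimum — the last reliably
trainable rate. The stopping rule is a pure function of the loss sequence,
so recorded runs replay exactly. Bound selection divides the suggested
maximum by 3.5 (repeated cycles) or 15 (single cycle), the midpoints of the
conventional 3–4 and 10–20 ranges; a manual constant-rate probe helper
covers the third, empirical selection style. Momentum and weight decay are
held constant (no cyclical momentum); the linear cycle variant is
implemented, discrete jumps are not, the two being reported equivalent in
the method's original exposition.

## Desk-scale study conditions

The reference training run — the stand-in for full-scale training of the
244 px, 4-block architecture on ~12k images, which is out of desk-scale
reach — uses: blocks (2, 2), growth rate 8, 16 stem channels, 64 px inputs;
50 training and 20 validation images per class rendered at 64 px; 10 epochs
of batch 16 (130 iterations); one-cycle bounds min = 0.003, max = 0.045
(ratio 15, consistent with the single-cycle bound-selection factor; the
maximum sits comfortably below the range-test divergence point of this
model/task, where mid-cycle rates near the divergence edge destabilized
training); final fraction 0.1. Under these conditions the run reaches ≥ 95%
validation accuracy and does so in no more iterations than a constant
learning rate fixed at the minimum bound — the qualitative cyclical-rate
speed-up claim, asserted at fixed seeds as a regression property rather
than a theorem. Problem sizes throughout the tests (64 px frames, ≤ 50
images per class, ≤ 10 epochs) were chosen once as the smallest scale at
which every stage still exercises its contract.

## Evaluation conventions

* Confusion matrix rows are true classes, columns predictions.
* Zero-division in precision/recall returns 0.0 with an `undefined` flag;
  classes are never dropped.
* Macro-F1 is the mean of per-class F1 values (not the F1 of macro-P/R);
  published report tables are internally inconsistent on this point, so only
  their self-consistent entries (the two per-class F1 rows and the macro
  precision) are used as worked examples.
* Micro-F1 sums TP/FP/FN across classes; for single-label multiclass data
  it equals accuracy, and the suite asserts that identity.
* Kappa with p_e = 1 (all marginal mass on one class) is flagged undefined
  unless the matrix is also perfect, in which case κ = 1.
* ROC is one-vs-rest per class; AUC is the trapezoidal area, equal to the
  Mann–Whitney concordance probability with half credit for ties; a class
  without both positives and negatives is flagged undefined.
* Report tables round half-up to two decimals; internal values keep full
  precision.

## Known limitations

* The numpy backend is single-threaded BLAS-bound; it is sized for the
  desk-scale configurations above, not for 244 px / 4-block training.
* Hue wraparound is unsupported by design; stains straddling the red seam
  would need a two-interval mask.
* The generator's separability guarantee makes the training acceptance
  bound achievable but also easy; it says nothing about class-imbalanced or
  low-contrast regimes.
* `evaluate` resizes every item to the model's input side and ignores any
  aspect-ratio difference, matching the pipeline's square-input convention.
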