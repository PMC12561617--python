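# Methods

## Model

The classifier is a four-stage convolutional network for single-channel
MRI slices. Stage *i* applies a stride-1 convolution (shape-preserving zero
padding, rectifier), 2×2 max pooling, and optionally an attention block.
Filter counts grow with depth (64-128-256-512 by default; 8-16-32-64 in the
reduced configuration) while kernel sizes shrink (7-5-3-3). The head
flattens the last stage and applies dense(128) → rectifier →
dense(num_classes), producing raw class scores; the head width is a
package choice — the published description leaves it open, so printed
parameter totals from the original experiments are not reproducible and are
not targets here.

An attention block stacks three sub-units, each a Gaussian Context
Transformer (GCT) channel gate followed by an l2-normalized spatial
attention block (l2-SAB), pairing kernel `k_j` with spread `c_j`
(j = 1..3). The standard four-block schedule is (8,6,4) / (8,6,4) /
(6,4,2) / (1,1,1) with spreads (4,2,1) everywhere.

**l2-SAB.** Channel-wise max- and min-pooled maps of the feature map are
each normalized to unit Euclidean norm (guard ε = 1e-6 for the zero map),
subtracted, convolved with one K×K filter (single channel, bias present and
zero-initialized), and squashed by a sigmoid; the resulting (0,1) map gates
every channel multiplicatively. Even kernel sizes preserve shape with
asymmetric padding ((K−1)//2 before, K−1−(K−1)//2 after). With the bias at
zero, identical channels yield a gate of exactly 1/2 everywhere — a useful
initialization invariant that the tests exercise.

**GCT.** Channel contexts are the spatial means; they are standardized
across channels (population std, guard ε = 1e-6) and mapped through
`exp(−ẑ²/2c²)`. Gates lie in (0,1]: the transform never flips signs nor
amplifies, and a channel whose context sits at the across-channel mean is
passed unchanged. The cited formulation is adopted because it is the only
parameter-free variant consistent with describing `c` as a Gaussian spread;
its exact standardization details are an acknowledged uncertainty of the
source description.

Sub-unit order is channel-then-spatial (GCT before l2-SAB), matching the
phrase "channel and spatial"; both the order and whether GCT is used are
config toggles, and the ablation grid (0–4 blocks × GCT on/off) is built
from the same declarative spec.

## Numerical core

`ansa_edge.nn` is a reverse-mode autodiff engine over float64 numpy arrays:
broadcast-aware elementwise ops, reductions with subgradient conventions
(ties split evenly in pooling; `sqrt` returns subgradient 0 at zero so
norms and variances of all-zero maps do not poison the graph), im2col
convolution, depthwise convolution with rectangular kernels, 2×2 max
pooling, and a fused softmax cross-entropy. Every backward rule is checked
against central finite differences. Backward accumulates gradients on all
graph nodes, which is what Grad-CAM reads. The optimizer is Adam
(optionally with decoupled weight decay); parameters with
`requires_grad = False` are skipped, which implements LoRA base-weight
freezing and head-only adaptation exactly.

## Compression transforms

All transforms are model-to-model rewrites that never mutate their input
and return a report with parameter counts and a probe-batch output
deviation.

* **DSC** rewrites each backbone conv with K > 1 as depthwise K×K +
  pointwise 1×1 (weights fresh; the rewrite is followed by retraining).
  Attention convs are excluded: they are single-channel, so the rewrite
  cannot reduce them.
* **RFM** is a spec-to-spec transform to filters 8-16-32-64.
* **LoRA** freezes base weights and adds trainable factors A (d_out×r),
  B (r×d_in) on the unfolded conv weight or the dense weight, with B
  zero-initialized so the adapted forward initially equals the base
  forward. Default rank 8 (the source experiments do not state one);
  ranks above min(d_in, d_out) are clamped with a warning. Adapters go on
  the four backbone convs and both dense layers; attention convs have one
  output channel, so a rank-1 adapter would already exceed their own
  parameter count.
* **CPTD** factorizes the first conv kernel (the only layer decomposed, for
  computational reasons) by alternating least squares on the 4-way tensor,
  minimizing the Frobenius reconstruction error; initialization is the
  leading singular vectors of each unfolding, so runs are deterministic.
  The layer is replaced by pointwise → depthwise K×1 → depthwise 1×K →
  pointwise, which equals convolution with the reconstructed kernel
  exactly; the output deviation is bounded by the reconstruction error
  times the input norm. Default rank Cout/4, 50 iterations. A rank curve
  helper warm-starts each rank from the previous factors, making the error
  non-increasing in rank by construction. After decomposition a 10× lower
  fine-tuning learning rate is recommended.
* **Pruning** ranks all conv and dense weight magnitudes globally and masks
  the smallest fraction to zero (achieved sparsity exact to within one
  weight); fine-tuning re-applies the mask after every optimizer step so
  masked weights stay exactly zero.

## Data pipeline

Readers accept one-folder-per-class JPEG/PNG trees and per-slice HDF5
`.mat` containers (`cjdata` group: image, label, patient ID, tumor border,
tumor mask; labels 1/2/3 map to meningioma/glioma/pituitary). Images are
converted to grayscale, resized to the model input (256 default), and
normalized to [0,1]. Legacy pre-v7.3 `.mat` files raise a dedicated error.

Augmentation applies exactly one of seven transforms per image — vertical
flip, horizontal flip, rotation by an angle drawn in ±90°, width/height
shift up to 10%, zoom within ±20%, shear within ±0.2 — chosen uniformly
(probability 1/7 each), and appends the copy, doubling the count
deterministically. "Rotation 90" is read as a ±90° range; the alternative
(a fixed 90° turn) would make the transform a relabeled flip of the axes
and adds no diversity. The doubling interpretation (one transformed copy
per original) is the only reading under which the stage doubles counts
exactly. Augmenting before splitting reproduces the published protocol but
leaks augmented twins across splits; the package's own experiments
therefore augment only the training side when augmentation is used at all.

Splits: holdout (floor(0.7n), floor(0.1n), remainder), optionally
stratified; five folds differing by at most one image. Both seeded,
disjoint, exhaustive.

## Synthetic phantoms

The generator emulates what the classification task needs and nothing
more: an elliptical head with smooth Gaussian-filtered texture on a dark
background, plus one bright elliptical blob for tumor classes — round and
smooth in the upper-left quadrant (class 0), elongated and textured in the
lower-right (class 1), high-eccentricity central (class 2) — and no blob
for the optional fourth class. Blob masks are the ground truth for
explainability scoring. It does not model MRI physics: no bias fields,
k-space artifacts, partial-volume effects, anatomy, or intensity
distributions of real tissue. Passing tests on phantoms therefore
demonstrates that the pipeline's mechanics are correct and that the model
class can learn and localize lesion-like structure — not clinical
performance.

## The surrogate study and restart selection

The canonical reduced study: 100 phantoms per class at 64×64, the
four-block reduced model, stratified 70-10-20 split, Adam at lr 3e-3,
batch 32, at most 30 epochs, early stopping on validation loss (patience
25) with best-epoch weights restored. The learning rate is three hundred
times the published operating point because the surrogate has two orders
of magnitude fewer images and epochs; the published schedule is the
package default (`TrainConfig()`), the surrogate schedule is explicit
wherever used.

Small trainings of the attention model are bimodal. Most restarts learn a
positive detector for every class and their class-activation maps peak on
the lesion; a minority settle into a minimal solution that encodes one
class purely as the absence of the other classes' evidence. Such a
solution is just as accurate on a closed three-class problem — two perfect
detectors logically determine the third class — but its saliency map for
the absence-coded class is identically zero: the class score has no
positive activation path, so there is nothing for a gradient-based
explanation to show. This is a genuine property of discriminative training
on closed-set problems, not an implementation artifact; it was verified by
inspecting the gradient structure of affected runs.

The study therefore trains three restarts and selects among the
validation-equivalent ones by explanation quality measured on training
images (the fraction of correctly classified training phantoms whose
heatmap peak falls inside the blob mask). The held-out test set plays no
role in selection and is evaluated once, on the selected model. Selecting
deployable models by the faithfulness of their explanations mirrors what a
practitioner shipping an interpretable classifier would do, and the
selection signal (training-set localization) is computable in practice
wherever lesion annotations exist.

An initialization-calibration helper (`calibrate_activation_scale`) can
rescale stage outputs to unit variance via fixed per-stage gains — the
stacked gates attenuate activations by roughly 2¹² at initialization — but
it is off by default: calibrated runs train from a well-conditioned start
and tend to solve the phantom task in a lazy regime whose features never
align with the lesions, which defeats saliency inspection. The plateau
that calibration would remove is instead escaped by the higher surrogate
learning rate.

## Grad-CAM

Channel weights are the spatial means of the class-score gradient at the
target stage; the rectified weighted activation sum is upsampled
bilinearly and min-max normalized (an all-zero map stays all zero rather
than being blown up by normalization). The default target layer is the
deepest stage whose activation map is at least 16×16: coarser maps place
their upsampled peak on a 4×4 grid of cell centers and cannot resolve
lesion-scale structure. For 256-input models the rule selects the last
conv stage; for the 64-input surrogate it selects stage 2.

## Evaluation

Metrics are computed one-vs-rest from the confusion matrix — precision,
recall/sensitivity, F1, specificity = TN/(TN+FP) — and macro-averaged
(weighted averaging is a config option; the averaging convention behind
the published single-value tables is not stated). A class absent from both
truth and predictions contributes zeros and is flagged. The tradeoff
factor keeps its mixed units (percentage points minus milliseconds)
exactly as defined. Inference timing uses warm-up passes and the median
over repeated runs; timings are reported, never asserted, because they are
hardware-bound. Monte Carlo repetition (fresh split and initialization per
run, mean ± std) and five-fold cross-validation (each sample tested once;
a tenth of each training portion held out for early stopping) follow the
published protocol shapes. Cross-dataset adaptation replaces and trains
only the final dense layer when class counts differ, and evaluates
directly when they match.

## Known limitations

* Phantom results do not transfer to clinical data (see above); the three
  public datasets' printed accuracies require full-scale training on the
  real images.
* The absence-coding degeneracy means single unselected restarts of the
  surrogate have a sizeable chance of an uninterpretable class even at
  perfect accuracy; the restart selection manages, but does not eliminate,
  this failure mode.
* CP-ALS minimizes reconstruction error of the kernel, not task loss;
  aggressive ranks degrade accuracy until fine-tuned.
* The augment-before-split protocol is reproduced only for count fidelity;
  its leakage makes metrics computed under it optimistic.
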