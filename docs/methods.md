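# Methods

## Model

A case is an ordered set of `n` single-channel 3-D volumes (views), one
binary label per case. The model has three parts.

**Shared 3-D residual encoder.** Every view is embedded by *one* shared
parameter set — a 3D-ResNet-10-style network: a stem
(3×3×3 Conv3D stride 2 → BN3D → ReLU → 2×2×2 MaxPool3D), four stages of one
basic residual block each, and adaptive average pooling to a single spatial
cell. A basic block computes `z = ReLU(F(v) + shortcut(v))` with
`F = BN(Conv(ReLU(BN(Conv(v)))))`; a 1×1×1 projection (conv + BN) replaces
the identity shortcut whenever channels or stride change so the addition is
shape-legal. The full-size configuration uses channels 64/128/256/512 and a
512-dimensional embedding; exact widths are configurable because only the
layer inventory and the 512-dim embedding are fixed points of the design.
Convolutions carry no bias (a batch-norm always follows). Weight sharing
across views keeps the parameter count independent of `n` and lets every
view contribute gradient signal to one encoder.

**Weighted feature fusion.** Each embedding `h_i` is scored by one shared
two-layer perceptron (embedding → 64 → 1) to a scalar logit; a softmax
across the `n` views of a case turns the logits into weights `w_i ≥ 0`,
`Σ w_i = 1`. The fused representation is the concatenation
`[w_1 h_1, …, w_n h_n]` of length `n × 512` in canonical view order.
The scorer's output layer is initialised near zero, so fusion starts at
uniform weights (`1/n`) and specialises gradually; without this the softmax
can collapse onto one view early in training and discard the other views'
evidence before the encoder has learned anything. Whether the scoring
network shares parameters across views was an open design point; sharing
was chosen for view-count flexibility and consistency with the shared
encoder.

**Classifier head.** A two-layer MLP maps the fused feature to 512 hidden
units (ReLU) and then to one logit; a sigmoid yields the tear probability.
A one-logit sigmoid head is algebraically equivalent to a two-way softmax
output for binary classification. Training minimises binary cross-entropy
`L(y, ŷ) = −[y ln ŷ + (1−y) ln(1−ŷ)]` (natural log), with `ŷ` clamped to
`[1e−7, 1−1e−7]` to avoid `log(0)`.

**Comparison fusion strategies** (for the ablation harness):

* `concat_feature` — unweighted concatenation (all weights 1);
* `label_average` — a per-view head produces `n` probabilities whose
  arithmetic mean is the decision;
* `label_weighted` — the same per-view probabilities combined as
  `Σ w_i p_i` with the learned softmax weights.

With `n = 1` all four strategies reduce to the same single-view
classifier.

## Training and evaluation

Adam with first-moment coefficient β₁ = 0.9, weight decay 1e−4 (added to
the gradient), initial learning rate 1e−4, batch size 32 cases, 100 epochs
— the standard protocol for this model family, and the package default.
After every epoch the validation AUC is computed in evaluation mode
(batch-norm running statistics); the snapshot with the highest validation
AUC is returned, earlier epoch winning ties. The global gradient norm is
clipped at 5 per step (configurable; disable with `clip_norm=None`): with
desk-scale datasets an occasional large step otherwise knocks training
into a memorisation regime. An optional positive-class loss weight
(default off) is available for imbalanced data. A "batch" counts cases;
each case contributes all its views.

AUC is the Mann–Whitney statistic (ties one half), computed via
scikit-learn. The reported operating point maximises Youden's
J = sensitivity + specificity − 1 over the ROC curve's thresholds, a case
being called positive when its probability is ≥ the threshold; ties in J
resolve to the lower threshold (the more sensitive operating point).

Everything is driven by explicit `numpy.random.Generator` seeds —
dataset generation, weight initialisation, batch shuffling — so a run is
bitwise reproducible on one machine/configuration.

## Implementation substrate

The network layers (Conv3D via im2col/GEMM, BatchNorm3D, MaxPool3D,
adaptive average pooling, linear layers), backpropagation and the Adam
optimiser are implemented directly on numpy with explicit per-layer
backward passes (`mvfusion.nn`). Activations and parameters are float32; a
module-level dtype switch allows float64 for the finite-difference gradient
checks in the test suite. Analytic gradients of every layer and of all four
end-to-end fusion strategies are verified against central differences.

## Synthetic phantom benchmark

The generator emulates the structural challenge of multi-view diagnosis:
label-relevant signal that is split across views so that no single view is
sufficient. Each view of a case is an independent noise volume: a smooth
low-frequency background field (Gaussian-filtered white noise, σ =
(1.5, 3, 3) voxels, scaled to sd 0.5) plus white Gaussian noise
(`noise_sd`, default 1). In a positive case an ellipsoidal lesion with a
smooth radial profile `exp(−3ρ²)` is added; its radii are drawn uniformly
from 0.28–0.40 of each extent and its centre from a jitter box of ±12.5 %
of each extent around the volume centre (the emulated structure occupies a
consistent central region, as the cruciate ligaments do in a knee
acquisition). View `v` renders only the lesion voxels whose in-plane angle
lies in an arc of width `view_informativeness[v] · 2π` centred at
`2πv/n` (edges feathered over 0.35 rad).

Benchmark defaults: 100 cases (70/10/20 stratified train/validation/test,
exact positive counts `round(0.5 · partition)`), 4 views of 16×32×32
voxels, amplitude 10, arcs of 0.2 per view. Two of these numbers deserve
justification:

* **Amplitude 10** (contrast-to-noise 10 at the lesion centre, bright-fluid
  contrast on a T2-like scale). A randomly initialised deep encoder with
  global average pooling strongly attenuates localised signal, and with
  only 70 training cases the optimiser must pick the planted signal up
  before the network memorises the training set. The amplitude is set so
  the signal survives that attenuation; at desk scale a fainter lesion
  turns every experiment into a test of optimisation luck rather than of
  the fusion architecture.
* **Arcs of 0.2** make the four rotated sectors disjoint: one view sees a
  fifth of the lesion, all views together see ~80 % of it plus feathering.
  This is the regime where the multi-view model's pooled evidence
  measurably exceeds the best single view's without either saturating the
  AUC ceiling of a 20-case test set.

The phantom experiments use a reduced encoder (channels 8/16/32/64,
64-dim embedding, 64-hidden head) and short schedules:
`TrainConfig.phantom` (lr 5e−4, batch 8, 20 epochs) for headline runs and
`TrainConfig.phantom_ablation` (lr 3e−4, batch 8, 20 epochs) for the
strategy comparisons — gentler, because the strategies' effective step
sizes differ with the scale of the fused feature (unweighted concatenation
feeds the head features `n`× larger than weighted fusion at uniform
weights) and a single shared config must keep all of them stable. The
full-size 512-dim configuration remains the library default.

**What passing phantom tests does and does not show.** The phantoms share
with real multi-view MRI the dimensionality, the cross-view split of
evidence, per-view noise, and a nuisance background field; they lack
anatomy, MR physics (bias fields, partial volume, scanner variation),
registration error, and label noise. Results on phantoms validate the
*mechanics* of the pipeline — encoding, fusion, training, selection,
evaluation — and the *relative* behaviour of fusion strategies, not
clinical performance.

With 20 test cases an AUC step is 0.01 and single training runs at this
scale have substantial variance; ordering comparisons between strategies
are therefore made on means over ≥5 seeded replicates, and the
feature-versus-label-fusion comparison is made between family means (the
two feature strategies' mean against the two label strategies' mean), as a
statistical tendency rather than a per-pair guarantee.

## Volume I/O and preprocessing

Loaders accept stacked-slice `.npy` arrays (one `(slices, H, W)` array per
view per case, the layout of public knee-MRI releases), DICOM series
directories (slices sorted by image position, falling back to filename
order with a warning; mixed series UIDs are an error; no
patient-identifying header fields are retained), and NIfTI volumes (the k
axis becomes depth). Axis convention is `(depth, height, width)`,
0-based.

`preprocess` normalises a raw volume to a fixed shape: in-plane trilinear
resampling to the target size, per-volume z-score, then depth
harmonisation by symmetric centre-crop or symmetric zero-padding (the odd
slice going to the trailing end). Padding happens after normalisation so
pad values sit at the mean; the z-score statistics exclude all-zero slices
(treated as padding), which makes the operation idempotent. A
constant-intensity volume normalises to all zeros with a logged warning
rather than an error. Z-scoring is the standard intensity normalisation
for MR, whose raw intensities are not comparable across scanners; depth
is cropped/padded rather than interpolated to preserve slice anatomy.
Datasets on disk are described by a case manifest (CSV: `case_id`,
`label`, one path column per view; column order fixes the canonical view
order — never filesystem order).

## Known limitations

* Batch-norm statistics early in training lag the parameters; with a
  10-case validation set the per-epoch validation AUC saturates quickly,
  so best-on-validation selection at desk scale can pick an under-trained
  snapshot. This is a property of the selection rule at small `n`, kept
  as-is because it is the protocol under study.
* The numpy substrate targets CPU-scale problems; the full-size encoder on
  256×256-slice clinical volumes would need minutes per batch and is
  provided for architectural fidelity, not throughput.
* The phantom generator plants additive, centrally located lesions; it
  cannot probe robustness to registration error or acquisition artefacts.
* No data augmentation is implemented; at phantom scale the effect of
  augmentation is entangled with the short schedules.
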