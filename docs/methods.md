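# Methods

`curriseg` trains a binary segmentation network from a small labeled pool
`D_l = {(x_i, y_i)}` and a larger unlabeled pool `D_u = {x_i}`, targeting
lesion-style data (polyp endoscopy, dermoscopic skin lesions) where masks are
expensive. The approach combines two unsupervised constraints around a
standard supervised objective, activated in two stages.

## Model

The backbone is a U-Net-style encoder–decoder: a stem of two 3×3 conv+ReLU
layers at `base_width` channels, `depth` max-pool/double-conv encoder levels
that double the channel count, and a mirrored decoder using nearest-neighbour
upsampling, a 1×1 channel-reducing convolution and skip concatenation. A 1×1
segmentation head maps the full-resolution decoder features to two class
logits (background, foreground); the foreground probability is the softmax of
channel 1. Input spatial dims must be divisible by `2**depth`.

One shared network plays every role: it segments full images, segments
patches, and supplies decoder feature maps at the configured `contrast_depths`
(default: the two coarsest decoder levels plus the final one). Each tapped
depth owns an independent projection head — a two-layer perceptron with
hidden width equal to `embed_dim` — whose outputs are L2-normalized, so all
similarities in the contrastive loss are cosine similarities in [−1, 1].
The architecture contains no stochastic layers (no dropout, no batch norm),
so inference is deterministic by construction and there is no train/eval mode
divergence.

## Objectives

The total loss is `L = α·L_cc + β·L_msc + L_sup`.

**Supervised** (labeled half of the batch):
`L_sup = ½(CE + Dice_loss)`, with CE the pixel-mean of `−log p(true class)`
(probability clamped at 1e-7) and the soft Dice loss
`1 − (2Σ p_fg y + ε)/(Σ p_fg + Σ y + ε)` with smoothing `ε = 1` so empty
masks are well-behaved.

**Curriculum consistency** (unlabeled half, stage 2): the image is split into
an `m(t)` grid of non-overlapping patches (row-major), each patch is segmented
independently by the same network, and its probability map is compared by MSE
against the aligned crop of the full-image probability map. `m(t)` is
piecewise constant over half-open phases: 0 before `stage1_epochs`, then the
patch counts `N = [4, 16, 25]` switching at the trigger epochs
`[t1, t2, t3] = [80, 160, 300]` (i.e. phases `[70,80)→4`, `[80,160)→16`,
`[160,300)→25` at benchmark scale). Fewer, larger patches make the
global–local agreement task easy; the task hardens as `m(t)` grows.

Two defaults here differ from the most literal reading of the defining
equation, and both are exposed as config flags:

* `cc_reduce="mean"` — the per-image loss averages the per-patch MSEs rather
  than summing them. A summed loss grows linearly in `m(t)` while `L_sup`
  does not, so with fixed `α = 1` the consistency term dominates the gradient
  precisely when the task becomes hardest. At desk scale this demonstrably
  collapses the predictor mid-stage-2 (validation Dice fell from ~61 to ~3
  in our seed-0 diagnostic run); the mean keeps the two terms on comparable
  scales across the whole curriculum. `"sum"` restores the literal form.
* `detach_global=True` — the full-image branch is treated as the target
  (stop-gradient), so the patches learn to match the better-informed global
  prediction and not vice versa. Without it the two branches can satisfy
  consistency jointly by drifting toward a constant map — the classic failure
  mode that teacher–student consistency schemes exist to prevent — and the
  full method then underperforms the supervised baseline at desk scale.

When the patch grid does not divide the image (e.g. a 5×5 grid on 64×64),
both the image and the global probability map are reflect-padded to the next
multiple of the grid and patch predictions are cropped back, keeping pixel
correspondence exact. Patches whose dims are not divisible by `2**depth` are
likewise reflect-padded before the backbone and their logits cropped back.

**Multi-scale contrastive constraint** (unlabeled half, stage 1): at each
tapped decoder depth k, the global feature map is average-pooled over the
grid cells and projected, giving one embedding per position i; each patch's
feature map is pooled whole (1×1 grid) and projected with the same depth-k
head. The per-scale loss is the InfoNCE form

    −(1/m) Σ_i log [ exp(g_i·p_i / τ) / (exp(g_i·p_i / τ) + Σ_{j≠i} exp(g_i·g_j / τ)) ]

with the patch embedding at the same position as positive and the *other
global positions* (exactly the printed denominator — not the other patches)
as negatives; `L_msc` sums the per-scale losses. With one position there are
no negatives and the loss is 0. Embeddings are unit-norm and the temperature
defaults to τ = 1; both together bound the exponents, so no further
stabilization is needed beyond a log-sum-exp evaluation.

Because `m(t) = 0` during stage 1 while `L_msc` is only active there, the
contrast uses the first curriculum count `n_1 = 4` (the easiest
decomposition) whenever `m(t) = 0`; when both terms are active in ablation
regimes it follows `m(t)`.

## Training

Two stages over `total_epochs = 300` (benchmark scale): `(α, β) = (0, 1)` for the
first `stage1_epochs = 70`, `(1, 0)` afterwards. Optimization is AdamW
(lr 1e-3, betas 0.9/0.999, decoupled weight decay at its conventional 1e-2 —
no value is pinned by the source, so the optimizer default stands), constant
learning rate. Batches hold `batch_size/2` labeled and `batch_size/2`
unlabeled images (default 4 + 4), each half drawn with replacement so the
small labeled pool recycles; an epoch is defined as `⌊|D_u| / (batch/2)⌋`
steps, i.e. over the larger pool. The unsupervised terms are averaged over
the unlabeled half of the batch. A non-finite loss term aborts training with
the offending term named. Inference is a single full-image forward pass — no
patching.

Validation for checkpoint selection is carved from the labeled pool (10%, at
least one image) when no explicit validation set is passed; the desk-scale
studies below pass a separate synthetic validation set instead, because at
4 labeled images a carve-out both starves training and makes the validation
estimate a single-image quantity. The best-validation-Dice checkpoint is
retained.

Ablation modes rewire the same loop: `no_cc` forces α = 0 throughout,
`no_msc` forces β = 0, `supervised_only` forces both; `full` is the two-stage
regime.

## Metrics

Per image: MAE is the mean absolute difference between the *continuous*
foreground probability map and the binary mask; IoU and Dice binarize at 0.5.
"mIoU" is foreground IoU averaged over images, which makes the identity
`dice = 2·iou/(1+iou)` hold per image; all aggregates are reported ×100.
The standard deviation is taken over repeated runs (different seeds), not
over images, matching the benchmark reporting convention. A squared-error
variant of the first metric is available (`mae_mode="sq"`).

## Synthetic data

The generator emulates the geometry of lesion segmentation: 1–3 smooth,
randomly deformed elliptical blobs (low-frequency radial perturbation of an
ellipse) whose color differs from the background by 0.2–0.35 per channel,
both regions textured with smoothed correlated noise plus fine grain, and a
light Gaussian blur (σ = 0.7 px) softening the boundary. Masks are exact and
binary; images are quantized to 8 bits so the in-memory arrays and the PNGs
round-trip exactly. Foreground fraction is constrained to [0.05, 0.4] by
rejection. Everything is deterministic in the seed.

What it does *not* emulate: specular highlights, instrument artifacts, hair,
vignetting, scale/illumination drift between acquisitions, ambiguous
boundaries, or any real lesion texture statistics. Passing the desk-scale
study therefore shows the training machinery works and that the two
constraints help when unlabeled structure is informative — it does not
predict absolute performance on clinical data.

## Desk-scale study conditions

The end-to-end checks and `scripts/acceptance.py` use: 40 training images at
64×64 with 10% labeled (4 images) plus 8 validation images; backbone width
16, depth 3; the scaled schedule stage1 = 10, `N = [4, 16, 25]`, triggers
`[12, 20, 30]`, 30 epochs; three seeds for both the full method and the
supervised-only baseline. These sizes keep a full six-run study in the
minutes range on one CPU while preserving every structural element of the
method (two stages, all three curriculum phases, multi-scale contrast).
With the defaults above, the full method improves validation Dice over
initialization for every seed and clearly outperforms the supervised-only
baseline on average; runs are bit-reproducible given the seed.

## Numerical choices and edge cases

* float32 throughout; gradients checked against central finite differences.
* CE clamps probabilities at 1e-7; Dice uses ε = 1; both configurable.
* Max-pool ties resolve to the first occurrence (deterministic backward).
* `m = 1` contrastive loss returns exactly 0 through a connected graph, so
  gradients exist (and are zero).
* Empty-vs-empty masks score IoU = Dice = 1 (perfect agreement).
* Reflect padding is used for all alignment padding so no artificial black
  borders enter the consistency targets.

## Known limitations

* CPU-only; problem sizes beyond ~100×100 with realistic widths are slow.
* Binary segmentation only; no boundary metrics (HD95/ASSD).
* No learning-rate schedule, EMA teacher, pseudo-labeling or uncertainty
  weighting — by design, these belong to the methods this approach is
  compared against.
* The desk-scale study is a structural analogue of the full benchmark, not a
  reproduction; absolute benchmark numbers require the real datasets and
  full-resolution 300-epoch training.
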