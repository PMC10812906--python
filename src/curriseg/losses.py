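"""Training objectives.

Three terms make up the overall objective L = alpha * L_cc + beta * L_msc + L_sup:

* L_cc  — curriculum consistency: the model segments the full image and each
  of its m(t) patches independently; the patch prediction is compared (MSE)
  with the aligned crop of the full-image probability map, summed over the
  m(t) patches of the current curriculum phase.
* L_msc — multi-scale contrastive constraint: at each configured decoder
  depth, projected embeddings of the global image grid are pulled toward
  the embedding of the spatially corresponding patch (positive pair) and
  pushed apart from the other global positions (negatives), in InfoNCE
  form, averaged over grid positions and summed over scales.
* L_sup — supervised loss on labeled images: the mean of pixel-wise
  cross-entropy and soft Dice loss.

All functions accept autodiff tensors (gradients flow) or plain numpy
arrays and return scalar tensors; call ``.item()`` for a float.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curriculum import crop_like
from .nn.tensor import Tensor, as_tensor, log_softmax


@dataclass(frozen=True)
class StageWeights:
    """Weights (alpha on L_cc, beta on L_msc) of the two-stage regime.

    Stage 1 uses (0, 1) — contrastive representation learning; stage 2 uses
    (1, 0) — curriculum consistency.  Arbitrary non-negative values are
    permitted for ablations.
    """

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError(f"weights must be non-negative, "
                             f"got alpha={self.alpha}, beta={self.beta}")

    @staticmethod
    def for_epoch(epoch: int, stage1_epochs: int) -> "StageWeights":
        if epoch < stage1_epochs:
            return StageWeights(alpha=0.0, beta=1.0)
        return StageWeights(alpha=1.0, beta=0.0)


@dataclass
class LossBreakdown:
    """Per-term values plus the weighted total, for logging."""

    l_cc: float
    l_msc: float
    l_sup: float
    total: float


def consistency_loss(global_probs, patch_probs, grid_shape,
                     reduce: str = "sum") -> Tensor:
    """Curriculum consistency loss for one image.

    Sum over the m = g*g patches of the per-patch MSE between the patch
    prediction and the aligned crop of the full-image probability map.
    Zero iff every patch prediction equals its crop.

    Parameters
    ----------
    global_probs : [classes, H, W] probability map of the full image.
    patch_probs : list of [classes, h, w] probability maps, row-major grid
        order, each matching the corresponding crop's shape.
    grid_shape : (g, g) decomposition grid.
    reduce : "sum" (as printed in the defining equation) or "mean" over
        patches.
    """
    g_r, g_c = grid_shape
    m = g_r * g_c
    if len(patch_probs) != m:
        raise ValueError(f"expected {m} patch predictions for grid "
                         f"{grid_shape}, got {len(patch_probs)}")
    global_probs = as_tensor(global_probs)
    total: Tensor | None = None
    for i, patch in enumerate(patch_probs):
        patch = as_tensor(patch)
        crop = crop_like(global_probs, i, grid_shape)
        if crop.shape != patch.shape:
            raise ValueError(f"patch {i} prediction shape {patch.shape} does "
                             f"not match aligned crop shape {crop.shape}")
        mse = ((crop - patch) ** 2.0).mean()
        total = mse if total is None else total + mse
    if reduce == "mean":
        total = total * (1.0 / m)
    elif reduce != "sum":
        raise ValueError(f"reduce must be 'sum' or 'mean', got {reduce!r}")
    return total


def contrastive_loss_at_scale(global_emb, patch_embs, tau: float = 1.0) -> Tensor:
    """InfoNCE contrast between global grid positions and their patches.

    For each grid position i, the positive similarity is the dot product of
    the global embedding at i with the embedding of patch i; the negatives
    are the dot products of global position i with every other global
    position j != i.  Returns the average over positions of

        -log( exp(s_pos_i / tau) /
              (exp(s_pos_i / tau) + sum_{j != i} exp(s_gg_ij / tau)) )

    With a single position there are no negatives and the loss is 0.
    Accepts `ProjectionEmbedding`-like objects (with a `.vectors` attribute)
    or raw [m, d] arrays/tensors.
    """
    G = as_tensor(getattr(global_emb, "vectors", global_emb))
    P = as_tensor(getattr(patch_embs, "vectors", patch_embs))
    if G.shape != P.shape:
        raise ValueError(f"global embeddings {G.shape} and patch embeddings "
                         f"{P.shape} must have matching [positions, dim]")
    m = G.shape[0]
    if m == 1:
        # keep the graph connected so gradients are defined (and zero)
        return ((G - P) * 0.0).sum()
    pos = (G * P).sum(axis=1) * (1.0 / tau)            # [m]
    sims = (G @ G.transpose(1, 0)) * (1.0 / tau)       # [m, m]
    eye = np.eye(m, dtype=np.float32)
    # score matrix rows: diagonal replaced by the positive similarity
    scores = sims * (1.0 - eye) + pos.reshape(m, 1) * eye
    return (scores.logsumexp(axis=1) - pos).mean()


def multiscale_contrastive_loss(per_scale_pairs, tau: float = 1.0) -> Tensor:
    """Sum of `contrastive_loss_at_scale` over decoder scales."""
    pairs = list(per_scale_pairs)
    if not pairs:
        raise ValueError("per_scale_pairs must be non-empty")
    total: Tensor | None = None
    for global_emb, patch_embs in pairs:
        term = contrastive_loss_at_scale(global_emb, patch_embs, tau=tau)
        total = term if total is None else total + term
    return total


def supervised_loss(logits, target_mask, eps: float = 1.0,
                    prob_clamp: float = 1e-7) -> Tensor:
    """Combined supervised loss: (CE + soft Dice loss) / 2.

    Cross-entropy is the pixel mean of -log p(true class); the soft Dice
    loss is 1 - (2 * sum(p_fg * y) + eps) / (sum(p_fg) + sum(y) + eps)
    computed on the foreground probability channel.  `eps` smooths the
    empty-target case; probabilities are clamped at `prob_clamp` before the
    log.

    logits: [classes, H, W] (foreground = channel 1) or batched
    [N, classes, H, W]; target_mask: matching [H, W] / [N, H, W] in {0, 1}.
    """
    logits = as_tensor(logits)
    batched = logits.ndim == 4
    if not batched:
        logits = logits.reshape((1,) + logits.shape)
    target = np.asarray(getattr(target_mask, "data", target_mask))
    if target.ndim == logits.ndim - 2:
        target = target[None]
    if target.shape != (logits.shape[0],) + logits.shape[2:]:
        raise ValueError(f"target shape {target.shape} does not match logits "
                         f"{logits.shape}")
    uniq = np.unique(target)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"target mask must be binary, found values {uniq}")
    target = target.astype(np.float32)

    log_probs = log_softmax(logits, axis=1)
    probs = log_probs.exp()
    # CE on the clamped probability of the true class
    onehot = np.stack([1.0 - target, target], axis=1)
    p_true = (probs * onehot).sum(axis=1)
    ce = -(p_true.clip(prob_clamp, 1.0).log()).mean()
    # soft Dice on the foreground channel
    p_fg = probs[:, 1]
    inter = (p_fg * Tensor(target)).sum()
    denom = p_fg.sum() + float(target.sum())
    dice_loss = 1.0 - (2.0 * inter + eps) / (denom + eps)
    return (ce + dice_loss) * 0.5


def combine(l_cc, l_msc, l_sup, weights: StageWeights) -> LossBreakdown:
    """Weighted total alpha*L_cc + beta*L_msc + L_sup, with the parts kept."""
    cc = float(getattr(l_cc, "data", l_cc))
    msc = float(getattr(l_msc, "data", l_msc))
    sup = float(getattr(l_sup, "data", l_sup))
    for name, v in (("l_cc", cc), ("l_msc", msc), ("l_sup", sup)):
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss term {name}: {v}")
    total = weights.alpha * cc + weights.beta * msc + sup
    return LossBreakdown(l_cc=cc, l_msc=msc, l_sup=sup, total=total)
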