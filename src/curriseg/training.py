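"""Two-stage semi-supervised training loop.

Stage 1 (epochs < stage1_epochs): the supervised loss plus the multi-scale
contrastive constraint (alpha=0, beta=1) build up the representation.
Stage 2: the curriculum consistency loss replaces it (alpha=1, beta=0) and
the patch count m(t) grows at the trigger epochs.  Each step draws half the
batch from the labeled pool and half from the unlabeled pool; the
unsupervised terms see only the unlabeled half.  Inference is a plain
full-image forward pass — no patching.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .curriculum import CurriculumSchedule, pad_to_grid, patch_count_at
from .data import ArrayDataset, sample_batch
from .losses import (StageWeights, combine, consistency_loss,
                     contrastive_loss_at_scale, supervised_loss)
from .metrics import MetricsReport, evaluate_model
from .model import BackboneConfig, SegmentationModel
from .nn.optim import AdamW
from .nn.tensor import Tensor, pad2d, softmax

CHECKPOINT_SCHEMA = "curriseg-checkpoint-v1"

ABLATION_MODES = ("full", "no_cc", "no_msc", "supervised_only")
# (keep_alpha, keep_beta) masks applied on top of the two-stage regime
_MODE_MASKS = {"full": (1.0, 1.0), "no_cc": (0.0, 1.0),
               "no_msc": (1.0, 0.0), "supervised_only": (0.0, 0.0)}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one training run."""

    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    schedule: CurriculumSchedule = field(default_factory=CurriculumSchedule)
    lr: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 8
    resolution: int = 320
    seed: int = 0
    eval_every: int = 10
    cc_reduce: str = "mean"        # mean over patches keeps Lcc on L_sup's
                                   # scale as m(t) grows ("sum" available)
    detach_global: bool = True     # global branch is the consistency target
                                   # (stop-gradient); False trains both ways
    tau: float = 1.0               # contrastive temperature (unit-norm dots)
    unsup_on_labeled: bool = False
    augment_hflip: bool = False

    def __post_init__(self):
        if self.batch_size % 2:
            raise ValueError(f"batch_size must be even, got {self.batch_size}")
        if self.resolution % self.backbone.divisor:
            raise ValueError(
                f"resolution {self.resolution} not divisible by 2**depth = "
                f"{self.backbone.divisor}")

    @property
    def total_epochs(self) -> int:
        return self.schedule.total_epochs

    @property
    def stage1_epochs(self) -> int:
        return self.schedule.stage1_epochs


@dataclass
class TrainResult:
    model: SegmentationModel
    loss_log: list[dict]            # per-step breakdown rows
    history: list[dict]             # per-evaluation metric rows
    best_dice: float
    best_epoch: int
    init_report: MetricsReport | None
    final_report: MetricsReport | None
    checkpoint_path: str | None = None


def _pad_to_multiple(images: np.ndarray, mult: int) -> np.ndarray:
    H, W = images.shape[-2:]
    ph, pw = (-H) % mult, (-W) % mult
    if ph == 0 and pw == 0:
        return images
    spec = [(0, 0)] * (images.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(images, spec, mode="reflect")


def _patch_stack(images: np.ndarray, g: int) -> tuple[np.ndarray, int, int]:
    """Row-major patches of every image: [N*g*g, C, H/g, W/g]."""
    N, C, H, W = images.shape
    ph, pw = H // g, W // g
    tiles = (images.reshape(N, C, g, ph, g, pw)
             .transpose(0, 2, 4, 1, 3, 5)
             .reshape(N * g * g, C, ph, pw))
    return tiles, ph, pw


def _unsup_losses(model: SegmentationModel, cfg: RunConfig, epoch: int,
                  unl_images: np.ndarray, unl_logits: Tensor,
                  unl_features, weights: StageWeights
                  ) -> tuple[Tensor | float, Tensor | float, int]:
    """Curriculum consistency + multi-scale contrastive terms for a batch.

    Returns (l_cc, l_msc, m_t); inactive terms come back as 0.0 so the
    corresponding gradients are exactly zero.
    """
    m_cc = patch_count_at(epoch, cfg.schedule)
    l_cc: Tensor | float = 0.0
    l_msc: Tensor | float = 0.0
    Bu = unl_images.shape[0]
    div = cfg.backbone.divisor

    if weights.alpha > 0.0 and m_cc > 0:
        g = math.isqrt(m_cc)
        global_probs = softmax(unl_logits, axis=1)
        if cfg.detach_global:
            global_probs = global_probs.detach()
        H, W = unl_images.shape[-2:]
        pad_h, pad_w = (-H) % g, (-W) % g
        if pad_h or pad_w:  # grid does not divide the image: reflect-pad
            global_probs = pad2d(global_probs, (0, pad_h, 0, pad_w), "reflect")
            imgs = pad_to_grid(unl_images, g)
        else:
            imgs = unl_images
        tiles, ph, pw = _patch_stack(imgs, g)
        patch_logits, _ = model.forward(_pad_to_multiple(tiles, div))
        patch_probs = softmax(patch_logits[:, :, :ph, :pw], axis=1)
        total = None
        for i in range(Bu):
            per_patch = [patch_probs[i * g * g + j] for j in range(g * g)]
            term = consistency_loss(global_probs[i], per_patch, (g, g),
                                    reduce=cfg.cc_reduce)
            total = term if total is None else total + term
        l_cc = total * (1.0 / Bu)

    if weights.beta > 0.0:
        # stage 1 has m(t) = 0; the contrast uses the easiest decomposition
        m = m_cc if m_cc > 0 else cfg.schedule.patch_counts[0]
        g = math.isqrt(m)
        tiles, ph, pw = _patch_stack(pad_to_grid(unl_images, g), g)
        _, patch_features = model.forward(_pad_to_multiple(tiles, div))
        total = None
        for k in range(len(cfg.backbone.contrast_depths)):
            g_emb = model.project_batch(unl_features.per_depth[k], (g, g), k)
            p_emb = model.project_batch(patch_features.per_depth[k], (1, 1), k)
            p_emb = p_emb.reshape(Bu, g * g, p_emb.shape[-1])
            for i in range(Bu):
                term = contrastive_loss_at_scale(g_emb[i], p_emb[i],
                                                 tau=cfg.tau)
                total = term if total is None else total + term
        l_msc = total * (1.0 / Bu)

    return l_cc, l_msc, m_cc


def train(cfg: RunConfig, labeled: ArrayDataset, unlabeled: ArrayDataset,
          val: ArrayDataset | None = None, run_dir=None,
          mode: str = "full", verbose: bool = False) -> TrainResult:
    """Run the two-stage loop and return the trained model plus logs.

    When no validation set is given, one is carved from the labeled pool
    (10%, at least one image).  `mode` selects the ablation wiring: "full",
    "no_cc" (alpha forced 0), "no_msc" (beta forced 0), or
    "supervised_only" (both 0).
    """
    if mode not in _MODE_MASKS:
        raise ValueError(f"mode must be one of {ABLATION_MODES}, got {mode!r}")
    keep_a, keep_b = _MODE_MASKS[mode]

    if val is None:
        n_val = max(1, round(0.1 * len(labeled)))
        if len(labeled) - n_val < 1:
            raise ValueError("labeled pool too small to carve a validation set;"
                             " pass `val` explicitly")
        val = ArrayDataset(labeled.images[:n_val], labeled.masks[:n_val],
                           labeled.stems[:n_val])
        labeled = ArrayDataset(labeled.images[n_val:], labeled.masks[n_val:],
                               labeled.stems[n_val:])
    if val.masks is None:
        raise ValueError("validation set must carry masks")

    rng = np.random.default_rng(cfg.seed)
    model = SegmentationModel(cfg.backbone, seed=cfg.seed)
    optimizer = AdamW(model.parameters(), lr=cfg.lr,
                      weight_decay=cfg.weight_decay)
    half = cfg.batch_size // 2
    steps_per_epoch = max(1, len(unlabeled) // half)

    run_dir = Path(run_dir) if run_dir is not None else None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)

    loss_log: list[dict] = []
    history: list[dict] = []
    init_report = evaluate_model(model, val.images, val.masks)
    history.append({"epoch": -1, **init_report.as_dict()})
    best_dice, best_epoch = -1.0, -1
    ckpt_path = str(run_dir / "best.ckpt.npz") if run_dir is not None else None

    for epoch in range(cfg.total_epochs):
        base = StageWeights.for_epoch(epoch, cfg.stage1_epochs)
        weights = StageWeights(alpha=base.alpha * keep_a,
                               beta=base.beta * keep_b)
        for step in range(steps_per_epoch):
            batch = sample_batch(labeled, unlabeled, cfg.batch_size, rng)
            lab_imgs, lab_masks = batch.labeled_images, batch.labeled_masks
            unl_imgs = batch.unlabeled_images
            if cfg.augment_hflip:
                flip = rng.random(cfg.batch_size) < 0.5
                lab_imgs = np.where(flip[:half, None, None, None],
                                    lab_imgs[..., ::-1], lab_imgs)
                lab_masks = np.where(flip[:half, None, None],
                                     lab_masks[..., ::-1], lab_masks)
                unl_imgs = np.where(flip[half:, None, None, None],
                                    unl_imgs[..., ::-1], unl_imgs)
            if cfg.unsup_on_labeled:
                unl_imgs = np.concatenate([unl_imgs, lab_imgs])

            stacked = np.concatenate([lab_imgs, unl_imgs])
            logits, features = model.forward(stacked)
            n_lab = len(lab_imgs)
            l_sup = supervised_loss(logits[:n_lab], lab_masks)

            need_unsup = (weights.alpha > 0.0 or weights.beta > 0.0)
            if need_unsup:
                from .model import MultiScaleFeatures
                unl_features = MultiScaleFeatures(
                    per_depth=[fm[n_lab:] for fm in features.per_depth],
                    final=features.final,
                    contrast_depths=features.contrast_depths)
                l_cc, l_msc, m_t = _unsup_losses(
                    model, cfg, epoch, unl_imgs, logits[n_lab:],
                    unl_features, weights)
            else:
                l_cc, l_msc = 0.0, 0.0
                m_t = patch_count_at(epoch, cfg.schedule)

            breakdown = combine(l_cc, l_msc, l_sup, weights)  # NaN guard + log
            total = l_sup
            if isinstance(l_cc, Tensor) and weights.alpha > 0.0:
                total = total + l_cc * weights.alpha
            if isinstance(l_msc, Tensor) and weights.beta > 0.0:
                total = total + l_msc * weights.beta

            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            loss_log.append({"epoch": epoch, "step": step,
                             "l_sup": breakdown.l_sup, "l_cc": breakdown.l_cc,
                             "l_msc": breakdown.l_msc,
                             "total": breakdown.total, "m_t": m_t})

        last = (epoch == cfg.total_epochs - 1)
        if (epoch + 1) % cfg.eval_every == 0 or last:
            report = evaluate_model(model, val.images, val.masks)
            history.append({"epoch": epoch, **report.as_dict()})
            if verbose:
                print(f"epoch {epoch}: dice {report.dice_mean:.2f} "
                      f"miou {report.miou_mean:.2f} mae {report.mae_mean:.2f}")
            if report.dice_mean > best_dice:
                best_dice, best_epoch = report.dice_mean, epoch
                if ckpt_path is not None:
                    save_checkpoint(ckpt_path, model, optimizer, epoch)

    final_report = evaluate_model(model, val.images, val.masks)
    if run_dir is not None:
        _write_logs(run_dir, loss_log, history)
        if best_epoch < 0:
            save_checkpoint(ckpt_path, model, optimizer, cfg.total_epochs - 1)
    return TrainResult(model=model, loss_log=loss_log, history=history,
                       best_dice=max(best_dice, final_report.dice_mean),
                       best_epoch=best_epoch, init_report=init_report,
                       final_report=final_report, checkpoint_path=ckpt_path)


def _write_logs(run_dir: Path, loss_log: list[dict],
                history: list[dict]) -> None:
    with open(run_dir / "losses.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "step", "l_sup",
                                                "l_cc", "l_msc", "total",
                                                "m_t"])
        writer.writeheader()
        writer.writerows(loss_log)
    with open(run_dir / "metrics.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "mae_mean",
                                                "miou_mean", "dice_mean",
                                                "mae_sd", "miou_sd",
                                                "dice_sd", "n_images"])
        writer.writeheader()
        writer.writerows(history)


# -------------------------------------------------------------- prediction

def predict(model: SegmentationModel, images: np.ndarray,
            threshold: float = 0.5, batch_size: int = 8
            ) -> tuple[np.ndarray, np.ndarray]:
    """Full-image inference: (binary masks, probability maps)."""
    probs = []
    for start in range(0, len(images), batch_size):
        probs.append(model.predict_probs(images[start:start + batch_size]))
    probs = np.concatenate(probs)
    return (probs >= threshold).astype(np.uint8), probs


# ------------------------------------------------------------- checkpoints

def save_checkpoint(path, model: SegmentationModel, optimizer: AdamW | None,
                    epoch: int) -> None:
    cfg = model.config
    payload = {
        "schema": np.array(CHECKPOINT_SCHEMA),
        "epoch": np.array(epoch),
        "config": np.array(json.dumps({
            "in_channels": cfg.in_channels, "base_width": cfg.base_width,
            "depth": cfg.depth, "num_classes": cfg.num_classes,
            "contrast_depths": list(cfg.contrast_depths),
            "embed_dim": cfg.embed_dim})),
    }
    for name, p in model.named_parameters():
        payload[f"param:{name}"] = p.data
    if optimizer is not None:
        for k, v in optimizer.state_dict().items():
            payload[f"opt:{k}"] = v
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[SegmentationModel, int]:
    with np.load(path, allow_pickle=False) as blob:
        schema = str(blob["schema"])
        if schema != CHECKPOINT_SCHEMA:
            raise ValueError(f"incompatible checkpoint schema {schema!r}; "
                             f"expected {CHECKPOINT_SCHEMA!r}")
        cfg = BackboneConfig(**{
            k: (tuple(v) if k == "contrast_depths" else v)
            for k, v in json.loads(str(blob["config"])).items()})
        model = SegmentationModel(cfg, seed=0)
        for name, p in model.named_parameters():
            p.data = blob[f"param:{name}"].astype(p.data.dtype)
        epoch = int(blob["epoch"])
    return model, epoch


# ---------------------------------------------------------------- ablation

def ablate(cfg: RunConfig, labeled: ArrayDataset, unlabeled: ArrayDataset,
           val: ArrayDataset | None = None,
           modes: tuple[str, ...] = ABLATION_MODES,
           seeds: tuple[int, ...] | None = None) -> dict[str, dict]:
    """Train each ablation mode on the same splits/seeds; tabulate metrics.

    Returns {mode: {"dice_mean": ..., "dice_sd": ..., "miou_mean": ...,
    "mae_mean": ..., "per_seed": [...]}} with means over seeds (x100 scale).
    """
    seeds = tuple(seeds) if seeds is not None else (cfg.seed,)
    table: dict[str, dict] = {}
    for mode in modes:
        if mode not in _MODE_MASKS:
            raise ValueError(f"unknown ablation mode {mode!r}")
        rows = []
        for seed in seeds:
            run_cfg = replace(cfg, seed=int(seed))
            result = train(run_cfg, labeled, unlabeled, val=val, mode=mode)
            rep = result.final_report
            rows.append({"seed": int(seed), "dice": rep.dice_mean,
                         "miou": rep.miou_mean, "mae": rep.mae_mean})
        dices = np.array([r["dice"] for r in rows])
        mious = np.array([r["miou"] for r in rows])
        maes = np.array([r["mae"] for r in rows])
        table[mode] = {
            "dice_mean": float(dices.mean()),
            "dice_sd": float(dices.std(ddof=0)) if len(rows) > 1 else None,
            "miou_mean": float(mious.mean()),
            "mae_mean": float(maes.mean()),
            "per_seed": rows,
        }
    return table
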