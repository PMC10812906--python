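"""Evaluation metrics: MAE, foreground IoU and Dice, percent-scale reporting.

MAE is computed on the continuous probability map (mean |p - y| over
pixels); IoU and Dice are computed on the map binarized at a threshold
(default 0.5).  "mIoU" is the foreground IoU averaged over images, which is
consistent with the algebraic identity dice = 2*iou / (1 + iou) holding
per image.  Aggregates are reported on a x100 percent scale; the standard
deviation is taken over repeated runs when several run results are given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MetricsReport:
    per_image: list[tuple[float, float, float]]  # (mae, iou, dice) per image
    mae_mean: float
    miou_mean: float
    dice_mean: float
    miou_sd: float | None
    dice_sd: float | None
    mae_sd: float | None
    n_images: int

    def as_dict(self) -> dict:
        return {
            "mae_mean": self.mae_mean, "miou_mean": self.miou_mean,
            "dice_mean": self.dice_mean, "mae_sd": self.mae_sd,
            "miou_sd": self.miou_sd, "dice_sd": self.dice_sd,
            "n_images": self.n_images,
        }


def binary_metrics(pred_probs: np.ndarray, gt_mask: np.ndarray,
                   threshold: float = 0.5,
                   mae_mode: str = "abs") -> tuple[float, float, float]:
    """(mae, iou, dice) for one image.

    pred_probs: [H, W] probabilities in [0, 1]; gt_mask: [H, W] in {0, 1}.
    `mae_mode` selects absolute ("abs") or squared ("sq") per-pixel error
    for the first component.
    """
    pred_probs = np.asarray(pred_probs, dtype=np.float64)
    gt = np.asarray(gt_mask)
    if pred_probs.shape != gt.shape:
        raise ValueError(f"pred shape {pred_probs.shape} != gt shape {gt.shape}")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    gt = (gt > 0).astype(np.float64)
    diff = np.abs(pred_probs - gt)
    if mae_mode == "sq":
        diff = diff ** 2
    elif mae_mode != "abs":
        raise ValueError(f"mae_mode must be 'abs' or 'sq', got {mae_mode!r}")
    mae = float(diff.mean())
    pred_bin = pred_probs >= threshold
    gt_bin = gt > 0
    inter = float(np.logical_and(pred_bin, gt_bin).sum())
    union = float(np.logical_or(pred_bin, gt_bin).sum())
    size_sum = float(pred_bin.sum() + gt_bin.sum())
    iou = inter / union if union > 0 else 1.0     # both empty: perfect match
    dice = 2.0 * inter / size_sum if size_sum > 0 else 1.0
    return mae, iou, dice


def aggregate(per_image: list[tuple[float, float, float]],
              runs: list[list[tuple[float, float, float]]] | None = None
              ) -> MetricsReport:
    """Mean metrics over images, x100; sd over repeated runs if supplied.

    `per_image` is the triple list of one run; `runs` optionally holds the
    triple lists of several repeated runs (e.g. different labeled-image
    draws), in which case the aggregate mean/sd are taken over the per-run
    means and `per_image` defaults to the first run.
    """
    if runs is not None:
        if not runs:
            raise ValueError("runs must be non-empty when given")
        means = np.array([[np.mean([t[i] for t in run]) for i in range(3)]
                          for run in runs])  # [n_runs, 3]
        mae_m, iou_m, dice_m = means.mean(axis=0) * 100.0
        sds = means.std(axis=0, ddof=0) * 100.0 if len(runs) > 1 else (None,) * 3
        per = list(per_image) if per_image else list(runs[0])
        return MetricsReport(per_image=per, mae_mean=float(mae_m),
                             miou_mean=float(iou_m), dice_mean=float(dice_m),
                             mae_sd=_opt(sds[0]), miou_sd=_opt(sds[1]),
                             dice_sd=_opt(sds[2]), n_images=len(per))
    if not per_image:
        raise ValueError("per_image must be non-empty")
    arr = np.asarray(per_image, dtype=np.float64)
    mae_m, iou_m, dice_m = arr.mean(axis=0) * 100.0
    return MetricsReport(per_image=list(per_image), mae_mean=float(mae_m),
                         miou_mean=float(iou_m), dice_mean=float(dice_m),
                         mae_sd=None, miou_sd=None, dice_sd=None,
                         n_images=len(per_image))


def _opt(v) -> float | None:
    return None if v is None else float(v)


def evaluate_model(model, images: np.ndarray, masks: np.ndarray,
                   threshold: float = 0.5, batch_size: int = 8,
                   mae_mode: str = "abs") -> MetricsReport:
    """Run a model over an image stack and aggregate the per-image metrics."""
    per = []
    for start in range(0, len(images), batch_size):
        probs = model.predict_probs(images[start:start + batch_size])
        for p, y in zip(probs, masks[start:start + batch_size]):
            per.append(binary_metrics(p, y, threshold=threshold,
                                      mae_mode=mae_mode))
    return aggregate(per)
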