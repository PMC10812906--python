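"""Run configuration: parsing, cross-field validation, run manifests.

A single structured YAML file is the source of truth for a run, with
sections ``model``, ``schedule``, ``optim``, ``data`` and ``train``.  Every
cross-field invariant (spatial divisibility, stage ordering, batch parity)
is checked up front so an accepted config cannot produce shape errors
mid-training.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .curriculum import CurriculumSchedule
from .model import BackboneConfig
from .training import RunConfig


class ConfigError(ValueError):
    """Invalid run configuration; message lists the offending keys."""


DEFAULT_DATA = {"image_dir": None, "mask_dir": None,
                "labeled_fraction": 0.2, "split_seed": 0}


def validate_config(raw: dict) -> tuple[RunConfig, dict]:
    """Build a validated RunConfig (plus the data section) from a raw dict."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    problems: list[str] = []
    model_raw = dict(raw.get("model", {}))
    sched_raw = dict(raw.get("schedule", {}))
    optim_raw = dict(raw.get("optim", {}))
    train_raw = dict(raw.get("train", {}))
    data_raw = {**DEFAULT_DATA, **raw.get("data", {})}

    try:
        backbone = BackboneConfig(**model_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"model: {exc}") from exc
    try:
        schedule = CurriculumSchedule(**sched_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"schedule: {exc}") from exc

    resolution = int(data_raw.pop("resolution", 320))
    if resolution % backbone.divisor:
        problems.append(
            f"data.resolution={resolution} not divisible by 2**model.depth="
            f"{backbone.divisor}")
    batch_size = int(train_raw.pop("batch_size", 8))
    if batch_size % 2:
        problems.append(f"train.batch_size={batch_size} must be even")
    if schedule.stage1_epochs > schedule.trigger_epochs[0]:
        problems.append(
            f"schedule.stage1_epochs={schedule.stage1_epochs} exceeds first "
            f"trigger {schedule.trigger_epochs[0]}")
    # the contrastive grid must divide every tapped decoder feature map
    g = math.isqrt(schedule.patch_counts[0])
    for k in backbone.contrast_depths:
        feat = resolution // 2 ** (backbone.depth - 1 - k)
        if feat % g:
            problems.append(
                f"contrast grid {g}x{g} (schedule.patch_counts[0]="
                f"{schedule.patch_counts[0]}) does not divide the depth-{k} "
                f"feature map ({feat}x{feat} at data.resolution={resolution})")
    if problems:
        raise ConfigError("invalid config:\n  " + "\n  ".join(problems))

    cfg = RunConfig(backbone=backbone, schedule=schedule,
                    lr=float(optim_raw.get("lr", 1e-3)),
                    weight_decay=float(optim_raw.get("weight_decay", 1e-2)),
                    batch_size=batch_size, resolution=resolution,
                    seed=int(train_raw.pop("seed", 0)),
                    eval_every=int(train_raw.pop("eval_every", 10)),
                    cc_reduce=str(train_raw.pop("cc_reduce", "mean")),
                    detach_global=bool(train_raw.pop("detach_global", True)),
                    tau=float(train_raw.pop("tau", 1.0)),
                    unsup_on_labeled=bool(train_raw.pop("unsup_on_labeled",
                                                        False)),
                    augment_hflip=bool(train_raw.pop("augment_hflip", False)))
    if train_raw:
        raise ConfigError(f"unknown train keys: {sorted(train_raw)}")
    return cfg, data_raw


def load_config(path) -> tuple[RunConfig, dict, dict]:
    """Parse a YAML file; returns (RunConfig, data section, raw echo)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg, data = validate_config(raw)
    return cfg, data, raw


def config_to_dict(cfg: RunConfig, data: dict | None = None) -> dict:
    out = {
        "model": asdict(cfg.backbone),
        "schedule": asdict(cfg.schedule),
        "optim": {"lr": cfg.lr, "weight_decay": cfg.weight_decay},
        "train": {"batch_size": cfg.batch_size, "seed": cfg.seed,
                  "eval_every": cfg.eval_every, "cc_reduce": cfg.cc_reduce,
                  "detach_global": cfg.detach_global, "tau": cfg.tau,
                  "unsup_on_labeled": cfg.unsup_on_labeled,
                  "augment_hflip": cfg.augment_hflip},
    }
    if data is not None:
        out["data"] = {**data, "resolution": cfg.resolution}
    return out


def write_manifest(run_dir, cfg: RunConfig, data: dict,
                   artifacts: dict | None = None) -> Path:
    """Write manifest.json: enough to re-launch an identical run."""
    from . import __version__
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config_to_dict(cfg, data),
        "seed": cfg.seed,
        "artifacts": artifacts or {},
    }
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def run_report(run_dir) -> str:
    """Human-readable summary of one run or of a directory of seeded runs.

    A run directory holds metrics.csv; a parent of several seeded runs
    yields one row with mean +/- sd over their final metrics.
    """
    run_dir = Path(run_dir)
    metric_files = ([run_dir / "metrics.csv"]
                    if (run_dir / "metrics.csv").exists()
                    else sorted(run_dir.glob("*/metrics.csv")))
    if not any(p.exists() for p in metric_files):
        raise FileNotFoundError(f"no metrics.csv under {run_dir}")

    finals = []
    for path in metric_files:
        rows = path.read_text().strip().splitlines()
        header = rows[0].split(",")
        last = dict(zip(header, rows[-1].split(",")))
        finals.append((float(last["mae_mean"]), float(last["miou_mean"]),
                       float(last["dice_mean"])))
    arr = np.array(finals)
    mean = arr.mean(axis=0)
    lines = ["method\tMAE\tmIoU\tDice"]
    if len(finals) > 1:
        sd = arr.std(axis=0, ddof=0)
        lines.append(f"{run_dir.name}\t{mean[0]:.2f}\t"
                     f"{mean[1]:.2f} ± {sd[1]:.2f}\t"
                     f"{mean[2]:.2f} ± {sd[2]:.2f}")
    else:
        lines.append(f"{run_dir.name}\t{mean[0]:.2f}\t{mean[1]:.2f}\t"
                     f"{mean[2]:.2f}")
    return "\n".join(lines)
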