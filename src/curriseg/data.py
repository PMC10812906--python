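"""Datasets: disk readers, labeled/unlabeled splits, the 1:1 semi-supervised
batch sampler, and a synthetic lesion-like image generator.

Directory layout: ``images/*.png|jpg`` and ``masks/*.png`` with matching
file stems; masks are single-channel with foreground white.  Images are
resized bilinearly, masks with nearest-neighbour (labels stay binary), and
masks are binarized at gray level 127.

The synthetic generator emulates the geometry of lesion segmentation data
(polyps, skin lesions): each image carries 1-3 smooth, randomly deformed
elliptical blobs whose color and texture differ from a noisy textured
background, together with the exact binary mask.  It is fully deterministic
given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

IMAGE_EXTS = (".png", ".jpg", ".jpeg")


@dataclass
class ArrayDataset:
    """An in-memory image stack: float images in [0,1], binary masks."""

    images: np.ndarray                 # [N, 3, H, W] float32
    masks: np.ndarray | None           # [N, H, W] uint8 in {0,1}, or None
    stems: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class SemiSupervisedBatch:
    labeled_images: np.ndarray         # [B_l, 3, H, W]
    labeled_masks: np.ndarray          # [B_l, H, W]
    unlabeled_images: np.ndarray       # [B_u, 3, H, W]


@dataclass
class SplitSpec:
    """Deterministic labeled/unlabeled split of an image directory."""

    labeled_fraction: float | None = None
    labeled_stems: list[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.labeled_fraction is None) == (self.labeled_stems is None):
            raise ValueError("give exactly one of labeled_fraction or "
                             "labeled_stems")
        if self.labeled_fraction is not None and not 0 < self.labeled_fraction < 1:
            raise ValueError(f"labeled_fraction must be in (0, 1), got "
                             f"{self.labeled_fraction}")


def _load_image(path: Path, resolution: int) -> np.ndarray:
    img = Image.open(path).convert("RGB")
    if img.size != (resolution, resolution):
        img = img.resize((resolution, resolution), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    return arr.transpose(2, 0, 1)


def _load_mask(path: Path, resolution: int) -> np.ndarray:
    img = Image.open(path).convert("L")
    if img.size != (resolution, resolution):
        img = img.resize((resolution, resolution), Image.NEAREST)
    return (np.asarray(img) > 127).astype(np.uint8)


def load_dataset(image_dir, mask_dir, split: SplitSpec,
                 resolution: int = 320) -> tuple[ArrayDataset, ArrayDataset]:
    """Read a directory pair into (labeled, unlabeled) datasets.

    The split is deterministic in ``split.seed``; every labeled stem must
    have a same-stem mask file.  Unlabeled images are returned without
    masks even when mask files exist.
    """
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    paths = sorted(p for p in image_dir.iterdir()
                   if p.suffix.lower() in IMAGE_EXTS)
    if not paths:
        raise FileNotFoundError(f"no images found in {image_dir}")
    stems = [p.stem for p in paths]
    by_stem = dict(zip(stems, paths))

    if split.labeled_stems is not None:
        labeled_stems = list(split.labeled_stems)
        unknown = sorted(set(labeled_stems) - set(stems))
        if unknown:
            raise ValueError(f"labeled stems not found in {image_dir}: {unknown}")
    else:
        rng = np.random.default_rng(split.seed)
        order = list(np.array(stems)[rng.permutation(len(stems))])
        n_labeled = max(1, round(split.labeled_fraction * len(stems)))
        labeled_stems = sorted(order[:n_labeled])
    unlabeled_stems = sorted(set(stems) - set(labeled_stems))
    if not labeled_stems or not unlabeled_stems:
        raise ValueError(f"split is degenerate: {len(labeled_stems)} labeled, "
                         f"{len(unlabeled_stems)} unlabeled")

    missing = [s for s in labeled_stems if not (mask_dir / f"{s}.png").exists()]
    if missing:
        raise FileNotFoundError(
            f"labeled images missing mask files in {mask_dir}: {missing}")

    lab_images = np.stack([_load_image(by_stem[s], resolution)
                           for s in labeled_stems])
    lab_masks = np.stack([_load_mask(mask_dir / f"{s}.png", resolution)
                          for s in labeled_stems])
    unl_images = np.stack([_load_image(by_stem[s], resolution)
                           for s in unlabeled_stems])
    labeled = ArrayDataset(lab_images, lab_masks, labeled_stems)
    unlabeled = ArrayDataset(unl_images, None, unlabeled_stems)
    return labeled, unlabeled


def sample_batch(labeled: ArrayDataset, unlabeled: ArrayDataset,
                 batch_size: int, rng: np.random.Generator
                 ) -> SemiSupervisedBatch:
    """Draw a half-labeled half-unlabeled batch (1:1 sampling probability).

    Each half is drawn with replacement from its pool, so the (typically
    much smaller) labeled pool recycles while epochs remain well defined
    over the larger pool.
    """
    if batch_size % 2:
        raise ValueError(f"batch_size must be even, got {batch_size}")
    half = batch_size // 2
    li = rng.integers(0, len(labeled), size=half)
    ui = rng.integers(0, len(unlabeled), size=half)
    return SemiSupervisedBatch(labeled_images=labeled.images[li],
                               labeled_masks=labeled.masks[li],
                               unlabeled_images=unlabeled.images[ui])


# --------------------------------------------------------------- synthetic

@dataclass(frozen=True)
class BlobParams:
    """Shape/appearance ranges for the synthetic lesion generator."""

    fg_frac: tuple[float, float] = (0.05, 0.4)   # mask foreground fraction
    n_blobs: tuple[int, int] = (1, 3)
    radius_frac: tuple[float, float] = (0.12, 0.30)  # base radius / resolution
    deform: float = 0.25                          # radial perturbation depth


def _blob_mask(rng: np.random.Generator, res: int,
               params: BlobParams) -> np.ndarray:
    yy, xx = np.mgrid[0:res, 0:res].astype(np.float64)
    mask = np.zeros((res, res), dtype=bool)
    n = int(rng.integers(params.n_blobs[0], params.n_blobs[1] + 1))
    for _ in range(n):
        cy, cx = rng.uniform(0.2 * res, 0.8 * res, size=2)
        r0 = rng.uniform(*params.radius_frac) * res
        aspect = rng.uniform(0.6, 1.4)
        theta0 = rng.uniform(0, 2 * np.pi)
        ct, st = np.cos(theta0), np.sin(theta0)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        dist = np.sqrt((u / aspect) ** 2 + (v * aspect) ** 2)
        ang = np.arctan2(v, u)
        wobble = np.zeros_like(ang)
        for k in range(2, 5):   # low-frequency boundary deformation
            wobble += rng.uniform(-1, 1) * np.sin(k * ang + rng.uniform(0, 2 * np.pi))
        mask |= dist < r0 * (1.0 + params.deform * wobble / 3.0)
    return mask


def _textured(rng: np.random.Generator, res: int, base: np.ndarray,
              smooth_amp: float, fine_amp: float) -> np.ndarray:
    """Base color + smooth correlated noise + fine grain, [3, res, res]."""
    smooth = np.stack([gaussian_filter(rng.standard_normal((res, res)),
                                       sigma=max(2.0, res / 16))
                       for _ in range(3)])
    smooth /= np.abs(smooth).max() + 1e-9
    fine = rng.standard_normal((3, res, res))
    return base[:, None, None] + smooth_amp * smooth + fine_amp * fine


def generate_synthetic(n_images: int, resolution: int, seed: int,
                       blob_params: BlobParams | None = None,
                       out_dir=None) -> ArrayDataset:
    """Generate lesion-like images with exact binary masks.

    Returns the in-memory dataset; when `out_dir` is given, also writes
    ``images/<stem>.png`` and ``masks/<stem>.png`` pairs there.  Fully
    deterministic in `seed`; every mask's foreground fraction falls inside
    ``blob_params.fg_frac`` (resampled until it does).
    """
    params = blob_params or BlobParams()
    rng = np.random.default_rng(seed)
    images, masks, stems = [], [], []
    for idx in range(n_images):
        for _ in range(200):
            mask = _blob_mask(rng, resolution, params)
            frac = mask.mean()
            if params.fg_frac[0] <= frac <= params.fg_frac[1]:
                break
        else:
            raise RuntimeError(f"could not hit fg_frac {params.fg_frac} in "
                               f"200 draws (image {idx})")
        bg_color = rng.uniform(0.35, 0.65, size=3)
        fg_color = np.clip(bg_color + rng.choice([-1, 1]) *
                           rng.uniform(0.2, 0.35, size=3), 0.0, 1.0)
        bg = _textured(rng, resolution, bg_color, 0.10, 0.03)
        fg = _textured(rng, resolution, fg_color, 0.08, 0.03)
        img = np.where(mask[None], fg, bg)
        img = gaussian_filter(img, sigma=(0, 0.7, 0.7))   # soften the boundary
        img = np.clip(img, 0.0, 1.0)
        # quantize to 8-bit so in-memory and PNG round-trip agree exactly
        img8 = np.round(img * 255.0).astype(np.uint8)
        images.append((img8.astype(np.float32) / 255.0))
        masks.append(mask.astype(np.uint8))
        stems.append(f"synth_{idx:04d}")

    dataset = ArrayDataset(np.stack(images), np.stack(masks), stems)
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
        for stem, img, mask in zip(stems, dataset.images, dataset.masks):
            arr = np.round(img.transpose(1, 2, 0) * 255.0).astype(np.uint8)
            Image.fromarray(arr).save(out_dir / "images" / f"{stem}.png")
            Image.fromarray(mask * 255).save(out_dir / "masks" / f"{stem}.png")
    return dataset
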