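"""U-Net-style segmentation backbone with multi-depth feature taps.

One shared encoder–decoder network serves three roles: it segments the full
image, segments each curriculum patch, and supplies per-depth decoder
features for the multi-scale contrastive constraint.  Each configured
contrast depth owns an independent projection head (a two-layer perceptron)
mapping pooled decoder features to unit-norm embeddings.

Decoder depth index 0 is the coarsest decoder level; index ``depth - 1`` is
the finest (full resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.layers import Conv2d, DoubleConv, Down, Linear, Module
from .nn.tensor import (Tensor, as_tensor, concat, l2_normalize, softmax,
                        upsample_nearest2x)


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters of the segmentation network."""

    in_channels: int = 3
    base_width: int = 16
    depth: int = 3
    num_classes: int = 2
    contrast_depths: tuple[int, ...] = None  # default: two coarsest + finest
    embed_dim: int = 32

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if self.contrast_depths is None:
            object.__setattr__(self, "contrast_depths",
                               tuple(sorted({0, 1, self.depth - 1})))
        else:
            object.__setattr__(self, "contrast_depths",
                               tuple(self.contrast_depths))
        for d in self.contrast_depths:
            if not 0 <= d < self.depth:
                raise ValueError(f"contrast depth {d} outside decoder levels "
                                 f"[0, {self.depth})")

    @property
    def divisor(self) -> int:
        """Spatial dims of any input must be divisible by this (2**depth)."""
        return 2 ** self.depth

    def channels_at(self, decoder_depth: int) -> int:
        """Channel count of the decoder feature map at a depth index."""
        return self.base_width * 2 ** (self.depth - 1 - decoder_depth)


@dataclass
class MultiScaleFeatures:
    """Decoder feature maps at the configured contrast depths.

    `per_depth[k]` is the [N, C_k, h_k, w_k] map for contrast depth k
    (ordered as in `config.contrast_depths`); `final` is the full-resolution
    feature map feeding the segmentation head.
    """

    per_depth: list
    final: Tensor
    contrast_depths: tuple[int, ...] = field(default_factory=tuple)


@dataclass
class ProjectionEmbedding:
    """Unit-norm embeddings of the grid cells of one feature map."""

    vectors: Tensor          # [rows * cols, embed_dim]
    grid_shape: tuple[int, int]

    def __post_init__(self):
        n, _ = self.vectors.shape
        rows, cols = self.grid_shape
        if n != rows * cols:
            raise ValueError(f"{n} embeddings do not match grid "
                             f"{self.grid_shape}")


class ProjectionHead(Module):
    """Two-layer perceptron; outputs are L2-normalized by the caller."""

    def __init__(self, in_dim: int, embed_dim: int, rng: np.random.Generator):
        self.fc1 = Linear(in_dim, embed_dim, rng=rng)
        self.fc2 = Linear(embed_dim, embed_dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class SegmentationModel(Module):
    """Shared U-Net backbone + segmentation head + per-depth projection heads."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        cfg = config
        self.config = config
        w = cfg.base_width
        self.stem = DoubleConv(cfg.in_channels, w, rng)
        self.downs = [Down(w * 2 ** i, w * 2 ** (i + 1), rng)
                      for i in range(cfg.depth)]
        # decoder level i (0 = coarsest): upsample, halve channels, fuse skip
        self.up_convs = []
        self.up_blocks = []
        for i in range(cfg.depth):
            ch_in = w * 2 ** (cfg.depth - i)       # channels arriving from below
            ch_out = ch_in // 2                    # matches the skip connection
            self.up_convs.append(Conv2d(ch_in, ch_out, kernel=1, rng=rng))
            self.up_blocks.append(DoubleConv(ch_in, ch_out, rng))
        self.seg_head = Conv2d(w, cfg.num_classes, kernel=1, rng=rng)
        self.proj_heads = [ProjectionHead(cfg.channels_at(d), cfg.embed_dim, rng)
                           for d in cfg.contrast_depths]

    # ----------------------------------------------------------------- fwd
    def forward(self, images) -> tuple[Tensor, MultiScaleFeatures]:
        """Segment a batch, returning logits and the multi-depth features.

        images: [N, C, H, W] with H and W divisible by 2**depth.
        """
        x = as_tensor(images)
        if x.ndim != 4:
            raise ValueError(f"expected [N, C, H, W] input, got shape {x.shape}")
        H, W = x.shape[2], x.shape[3]
        div = self.config.divisor
        if H % div or W % div:
            raise ValueError(
                f"input spatial dims {H}x{W} must be divisible by "
                f"2**depth = {div}")
        skips = [self.stem(x)]
        for down in self.downs:
            skips.append(down(skips[-1]))
        feat = skips.pop()                       # bottleneck
        decoder_feats = []
        for conv1, block in zip(self.up_convs, self.up_blocks):
            feat = conv1(upsample_nearest2x(feat))
            feat = block(concat([feat, skips.pop()], axis=1))
            decoder_feats.append(feat)           # coarsest first
        logits = self.seg_head(feat)
        features = MultiScaleFeatures(
            per_depth=[decoder_feats[d] for d in self.config.contrast_depths],
            final=feat,
            contrast_depths=self.config.contrast_depths)
        return logits, features

    def predict_probs(self, images) -> np.ndarray:
        """Foreground probability maps, [N, H, W] in [0, 1]."""
        logits, _ = self.forward(images)
        return softmax(logits, axis=1).data[:, 1]

    # ---------------------------------------------------------- projection
    def project_batch(self, features_at_depth_k: Tensor,
                      grid_shape: tuple[int, int], scale_index: int) -> Tensor:
        """Pooled + projected unit-norm embeddings, [N, rows*cols, embed_dim].

        Average-pools the [N, C, h, w] feature map over each grid cell,
        applies that scale's projection head, and L2-normalizes.
        """
        feat = as_tensor(features_at_depth_k)
        N, C, h, w = feat.shape
        rows, cols = grid_shape
        if h % rows or w % cols:
            raise ValueError(f"grid {grid_shape} does not divide feature "
                             f"dims {h}x{w}")
        hc, wc = h // rows, w // cols
        pooled = (feat.reshape(N, C, rows, hc, cols, wc)
                  .mean(axis=(3, 5))             # [N, C, rows, cols]
                  .transpose(0, 2, 3, 1)
                  .reshape(N, rows * cols, C))
        emb = self.proj_heads[scale_index](pooled)
        return l2_normalize(emb, axis=-1)

    def project(self, features_at_depth_k, grid_shape: tuple[int, int],
                scale_index: int = 0) -> ProjectionEmbedding:
        """Project one feature map ([C, h, w]) into grid-cell embeddings."""
        feat = as_tensor(features_at_depth_k)
        if feat.ndim != 3:
            raise ValueError(f"expected [C, h, w] feature map, got {feat.shape}")
        batched = self.project_batch(feat.reshape((1,) + feat.shape),
                                     grid_shape, scale_index)
        return ProjectionEmbedding(vectors=batched.reshape(batched.shape[1:]),
                                   grid_shape=grid_shape)
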