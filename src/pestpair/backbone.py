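"""Hybrid CNN + spatial-Transformer backbone.

A stack of stride-2 conv -> batch-norm -> GELU stages extracts local texture
features ([B, C, H, W]); the map is flattened row-major into N = H*W tokens,
projected to the embedding width, given learned positional codes, and passed
through pre-norm multi-head self-attention layers that model long-range
context between image regions.

Two profiles are built in: ``full`` (224px input, 4 stages ending at 256
channels on a 14x14 grid, d=256, 8 heads, 2 layers) and a CPU-friendly
``desk`` profile (64px input, 3 stages to 64 channels on 8x8, d=64, 2 heads,
1 layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    Linear,
    Module,
    Parameter,
    Tensor,
    TransformerEncoderLayer,
    as_tensor,
)

__all__ = ["BackboneConfig", "ConvStack", "STransformer", "patchify", "unpatchify", "HybridBackbone"]


@dataclass(frozen=True)
class BackboneConfig:
    profile: str = "full"
    stage_channels: tuple[int, ...] = (64, 128, 192, 256)
    embed_dim: int = 256
    n_heads: int = 8
    n_layers: int = 2
    canvas: int = 224
    ff_mult: int = 4
    avgpool_smoothing: bool = False  # 2x2 stride-1 mean smoothing; preserves N

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} must be divisible by n_heads {self.n_heads}"
            )

    @property
    def stride(self) -> int:
        return 2 ** len(self.stage_channels)

    @property
    def patch_grid(self) -> int:
        return self.canvas // self.stride

    @property
    def n_tokens(self) -> int:
        return self.patch_grid**2

    @classmethod
    def full(cls) -> "BackboneConfig":
        return cls()

    @classmethod
    def desk(cls) -> "BackboneConfig":
        return cls(
            profile="desk",
            stage_channels=(32, 48, 64),
            embed_dim=64,
            n_heads=2,
            n_layers=1,
            canvas=64,
            ff_mult=2,
        )


class ConvStack(Module):
    """Stride-2 conv/BN/GELU stages reducing the canvas to the patch grid."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.convs: list[Conv2d] = []
        self.norms: list[BatchNorm2d] = []
        in_ch = 3
        for out_ch in config.stage_channels:
            self.convs.append(Conv2d(in_ch, out_ch, rng, kernel=3, stride=2, pad=1))
            self.norms.append(BatchNorm2d(out_ch))
            in_ch = out_ch

    def __call__(self, images: Tensor) -> Tensor:
        x = as_tensor(images)
        side = x.shape[-1]
        if x.shape[-2] != side:
            raise ValueError("input images must be square")
        if side % self.config.stride != 0:
            raise ValueError(
                f"input side {side} not divisible by total conv stride {self.config.stride}"
            )
        for conv, norm in zip(self.convs, self.norms):
            x = norm(conv(x)).gelu()
        if self.config.avgpool_smoothing:
            x = _avgpool2x2_same(x)
        return x


def _avgpool2x2_same(x: Tensor) -> Tensor:
    """2x2 stride-1 average pooling with edge replication: token count preserved."""
    b, c, h, w = x.shape
    idx_y = np.minimum(np.arange(h) + 1, h - 1)
    idx_x = np.minimum(np.arange(w) + 1, w - 1)
    data = x.data
    pooled = (
        data
        + data[:, :, idx_y, :]
        + data[:, :, :, idx_x]
        + data[:, :, idx_y][:, :, :, idx_x]
    ) / 4.0

    def bwd(g):
        acc = g / 4.0
        gx = acc.copy()
        np.add.at(gx, (slice(None), slice(None), idx_y), acc)
        np.add.at(gx, (slice(None), slice(None), slice(None), idx_x), acc)
        np.add.at(gx, (slice(None), slice(None), idx_y[:, None], idx_x[None, :]), acc)
        x._accum(gx)

    return Tensor._make(pooled, (x,), bwd)


class Patchify(Module):
    """Row-major flatten of spatial positions into tokens, plus projection
    to the embed width and learned positional codes."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        channels = config.stage_channels[-1]
        self.proj = (
            Linear(channels, config.embed_dim, rng) if channels != config.embed_dim else None
        )
        self.pos = Parameter(0.02 * rng.standard_normal((config.n_tokens, config.embed_dim)))

    def __call__(self, fmap: Tensor, add_pos: bool = True) -> Tensor:
        seq = patchify(fmap)
        if self.proj is not None:
            seq = self.proj(seq)
        if add_pos:
            seq = seq + self.pos
        return seq


def patchify(fmap: Tensor | np.ndarray) -> Tensor:
    """[B, C, H, W] -> [B, N, C] with N = H*W in row-major (y, then x) order."""
    fmap = as_tensor(fmap)
    b, c, h, w = fmap.shape
    return fmap.reshape(b, c, h * w).transpose(0, 2, 1)


def unpatchify(seq: Tensor | np.ndarray, h: int, w: int) -> np.ndarray:
    """Inverse of :func:`patchify` (positional codes and projection aside)."""
    seq = as_tensor(seq)
    b, n, c = seq.shape
    if n != h * w:
        raise ValueError("token count does not match grid")
    return seq.data.transpose(0, 2, 1).reshape(b, c, h, w)


class STransformer(Module):
    """Spatial Transformer: stacked pre-norm self-attention blocks."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.layers = [
            TransformerEncoderLayer(config.embed_dim, config.n_heads, config.ff_mult, rng)
            for _ in range(config.n_layers)
        ]

    def __call__(self, seq: Tensor) -> Tensor:
        for layer in self.layers:
            seq = layer(seq)
        return seq


class HybridBackbone(Module):
    """ConvStack -> Patchify(+pos) -> STransformer, the full image encoder."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator, use_transformer: bool = True):
        super().__init__()
        self.config = config
        self.conv = ConvStack(config, rng)
        self.patchify = Patchify(config, rng)
        self.transformer = STransformer(config, rng) if use_transformer else None

    def __call__(self, images: Tensor, add_pos: bool = True) -> Tensor:
        fmap = self.conv(images)
        seq = self.patchify(fmap, add_pos=add_pos)
        if self.transformer is not None:
            seq = self.transformer(seq)
        return seq
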