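"""Spatial-information-retained (SIR) multi-scale feature extraction.

Feature maps from the early backbone stages carry fine spatial detail on
large grids (/4, /8, /16) while the last stage sees the whole image on a
coarse /32 grid.  Instead of average-pooling the early maps down to
vectors — which discards their spatial layout — the SIR extractor:

1. rescales each stage-i map channel-wise with a 1x1 conv-BN-ReLU unit to
   O_i channels (defaults O = (16, 32, 64));
2. splits the rescaled map into non-overlapping chunks of the stage-4
   spatial size (H/32, W/32) — giving k_i = 64, 16, 4 chunks at scales
   1..3 regardless of input side;
3. stacks the chunks along the channel axis in row-major chunk order
   (a space-to-depth move: channel block j is chunk j), yielding maps of
   16*64, 32*16 and 64*4 channels on the /32 grid;
4. projects each stacked map, and the raw stage-4 map, to 128 channels
   with another 1x1 conv-BN-ReLU unit, and concatenates the four in scale
   order — a [128*4, H/32, W/32] feature holding both local detail and
   global context.

The rearrangement is a bijection on elements: nothing is pooled away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import BackboneConfig, ResidualBackbone, PRESETS
from .nn import Tensor, concat
from .nn import functional as F

__all__ = ["ChunkGrid", "spatial_split", "chunk_concat", "reassemble",
           "space_to_depth", "SIRExtractor"]


@dataclass
class ChunkGrid:
    """Row-major collection of (B, C, th, tw) chunks tiling a feature map."""

    chunks: list          # list of np.ndarray, length grid_h * grid_w
    grid_h: int
    grid_w: int

    def __len__(self):
        return len(self.chunks)


def _check_divisible(h, w, th, tw):
    if h % th or w % tw:
        raise ValueError(
            f"spatial size ({h},{w}) not divisible by chunk size ({th},{tw})")


def spatial_split(s_prime, target_h: int, target_w: int) -> ChunkGrid:
    """Split a (B,C,h,w) map into non-overlapping (target_h, target_w) chunks.

    Chunks are ordered row-major: row index m outer, column index n inner.
    Together they tile the map exactly once.
    """
    x = s_prime.data if isinstance(s_prime, Tensor) else np.asarray(s_prime)
    b, c, h, w = x.shape
    _check_divisible(h, w, target_h, target_w)
    gh, gw = h // target_h, w // target_w
    chunks = [
        x[:, :, m * target_h:(m + 1) * target_h, n * target_w:(n + 1) * target_w]
        for m in range(gh) for n in range(gw)
    ]
    return ChunkGrid(chunks=chunks, grid_h=gh, grid_w=gw)


def chunk_concat(grid: ChunkGrid) -> np.ndarray:
    """Stack chunks channel-wise: output channel block j (size C) = chunk j."""
    shapes = {ch.shape for ch in grid.chunks}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent chunk shapes: {sorted(shapes)}")
    return np.concatenate(grid.chunks, axis=1)


def reassemble(grid: ChunkGrid) -> np.ndarray:
    """Inverse of `spatial_split`: place chunks back on the full grid."""
    b, c, th, tw = grid.chunks[0].shape
    out = np.empty((b, c, grid.grid_h * th, grid.grid_w * tw),
                   dtype=grid.chunks[0].dtype)
    for m in range(grid.grid_h):
        for n in range(grid.grid_w):
            out[:, :, m * th:(m + 1) * th, n * tw:(n + 1) * tw] = \
                grid.chunks[m * grid.grid_w + n]
    return out


def space_to_depth(x: Tensor, target_h: int, target_w: int) -> Tensor:
    """Differentiable fused split+concat (equals chunk_concat(spatial_split(x))).

    (B, C, gh*th, gw*tw) -> (B, gh*gw*C, th, tw) with channel block j equal
    to chunk j in row-major order.
    """
    b, c, h, w = x.shape
    _check_divisible(h, w, target_h, target_w)
    gh, gw = h // target_h, w // target_w
    y = x.reshape(b, c, gh, target_h, gw, target_w)
    y = y.transpose(0, 2, 4, 1, 3, 5)          # (B, gh, gw, C, th, tw)
    return y.reshape(b, gh * gw * c, target_h, target_w)


class SIRExtractor(nn.Module):
    """Backbone + SIR rearrangement producing the multi-scale feature.

    Parameters
    ----------
    backbone_config : BackboneConfig or preset name ("resnet50", "reduced")
    rescale_channels : O_i for scales 1..3 (default (16, 32, 64))
    out_channels : per-scale channels after the final 1x1 projection
        (default 128, so the concatenated feature has 128*4 = 512 channels)
    seed : weight-init seed
    """

    def __init__(self, backbone_config="resnet50",
                 rescale_channels=(16, 32, 64), out_channels: int = 128,
                 seed: int = 0):
        super().__init__()
        if isinstance(backbone_config, str):
            backbone_config = PRESETS[backbone_config]
        self.backbone = ResidualBackbone(backbone_config, seed=seed)
        self.rescale_channels = tuple(rescale_channels)
        self.out_channels = out_channels
        rng = np.random.default_rng(seed + 1)
        stage_ch = backbone_config.stage_channels
        # k_i chunk counts are side-independent: the /4, /8, /16 grids hold
        # 8x8, 4x4, 2x2 chunks of the /32 grid size.
        self.chunk_counts = (64, 16, 4)
        for i in range(3):
            setattr(self, f"rescale{i + 1}",
                    nn.ConvBNReLU(stage_ch[i], self.rescale_channels[i], rng=rng))
            stacked = self.rescale_channels[i] * self.chunk_counts[i]
            setattr(self, f"project{i + 1}",
                    nn.ConvBNReLU(stacked, out_channels, rng=rng))
        self.project4 = nn.ConvBNReLU(stage_ch[3], out_channels, rng=rng)

    @property
    def feature_channels(self) -> int:
        return 4 * self.out_channels

    def rescale(self, i: int, s_i: Tensor) -> Tensor:
        """Channel-rescale stage-i activations to O_i channels (1x1 conv-BN-ReLU)."""
        return getattr(self, f"rescale{i}")(s_i)

    def forward(self, batch: Tensor) -> Tensor:
        s = self.backbone(batch)
        th, tw = s[3].shape[2], s[3].shape[3]
        feats = []
        for i in range(3):
            sp = self.rescale(i + 1, s[i])
            stacked = space_to_depth(sp, th, tw)
            feats.append(getattr(self, f"project{i + 1}")(stacked))
        feats.append(self.project4(s[3]))
        return concat(feats, axis=1)


def sir_extract(extractor: SIRExtractor, batch: Tensor) -> Tensor:
    """The full SIR pipeline on an image batch -> (B, 4*out, H/32, W/32)."""
    return extractor(batch)
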