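"""50-layer residual backbone exposing per-stage activations.

The quality network reads activations from the last convolutional layer of
each of the four residual stages (strides /4, /8, /16, /32 relative to the
input).  At the standard width the stage channel counts are 256, 512, 1024
and 2048 — the bottleneck layout of the 50-layer residual network.  A
"reduced" preset with the same topology but narrow stages is provided for
CPU-scale experiments; it preserves every shape contract that matters
downstream (stride pattern, four stages, /32 output grid).

Weights are He-initialized from a caller-supplied seed; no pretrained
checkpoint is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F

EXPANSION = 4


@dataclass(frozen=True)
class BackboneConfig:
    """Topology of the residual backbone.

    widths: bottleneck (inner) width per stage; stage output channels are
    ``EXPANSION * width``.  ``blocks``: residual blocks per stage.
    """

    stem: int = 64
    widths: tuple = (64, 128, 256, 512)
    blocks: tuple = (3, 4, 6, 3)

    @property
    def stage_channels(self) -> tuple:
        return tuple(EXPANSION * w for w in self.widths)


PRESETS = {
    "resnet50": BackboneConfig(),
    "reduced": BackboneConfig(stem=8, widths=(4, 8, 16, 32), blocks=(1, 1, 1, 1)),
}


class Bottleneck(nn.Module):
    """1x1 reduce -> 3x3 -> 1x1 expand, with projection shortcut when needed."""

    def __init__(self, cin: int, width: int, stride: int, *, rng):
        super().__init__()
        cout = EXPANSION * width
        self.conv1 = nn.Conv2d(cin, width, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, cout, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(cout)
        else:
            self.down_conv = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        sc = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (y + sc).relu()


class ResidualBackbone(nn.Module):
    def __init__(self, config: BackboneConfig | str = "resnet50", seed: int = 0):
        super().__init__()
        if isinstance(config, str):
            config = PRESETS[config]
        self.config = config
        rng = np.random.default_rng(seed)
        self.stem_conv = nn.Conv2d(3, config.stem, 7, stride=2, padding=3,
                                   bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(config.stem)
        cin = config.stem
        self.stages = []
        for si, (w, nblocks) in enumerate(zip(config.widths, config.blocks)):
            blocks = []
            for bi in range(nblocks):
                stride = 2 if (si > 0 and bi == 0) else 1
                blocks.append(Bottleneck(cin, w, stride, rng=rng))
                cin = EXPANSION * w
            stage = nn.Sequential(*blocks)
            setattr(self, f"stage{si + 1}", stage)
            self.stages.append(stage)

    def forward(self, x: Tensor) -> tuple:
        """Return (s1, s2, s3, s4) stage activations for an image batch."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (B,3,H,W) input, got {tuple(x.shape)}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(
                f"input side must be divisible by 32, got {x.shape[2]}x{x.shape[3]}")
        y = self.stem_bn(self.stem_conv(x)).relu()
        y = F.max_pool2d(y, 3, 2, 1)
        outs = []
        for stage in self.stages:
            y = stage(y)
            outs.append(y)
        return tuple(outs)


def extract_multiscale(backbone: ResidualBackbone, batch: Tensor) -> tuple:
    """Stage-wise activations s_i = f(X | Stage_i), i = 1..4."""
    return backbone(batch)
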