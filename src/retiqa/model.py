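"""Quality-prediction model variants: attention, mask gating, aggregation.

The network predicts one binary quality item (uneven illumination/color,
blur, low contrast, or overall) per model.  The prediction is

    q_hat = g( f(X; theta) * att(f(X; theta); gamma) ; delta )

where f is the feature extractor (stage-4 map for baseline variants, the
SIR multi-scale feature for the MS variants), `att` is an optional spatial
weighting, and g is global average pooling followed by a fully-connected
stack ending in a scalar logit.  The loss is binary cross-entropy of
sigmoid(logit) against the 0/1 label.

Five variants are wired, named after what they add to the baseline:

- ``BL``                 stage-4 -> GAP -> FC
- ``BL+MASK``            stage-4 gated by the eye-area mask -> GAP -> FC
- ``BL+SpatialAtt``      stage-4 weighted by a learned spatial map
- ``BL+SpatialAtt+MS``   SIR feature weighted by a learned spatial map
- ``BL+SelfAtt+MS``      SIR feature transformed by a non-local
                         self-attention block
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import BackboneConfig, PRESETS
from .nn import Tensor
from .nn import functional as F
from .sir import SIRExtractor

VARIANTS = ("BL", "BL+MASK", "BL+SpatialAtt", "BL+SpatialAtt+MS", "BL+SelfAtt+MS")

__all__ = ["VARIANTS", "ModelSpec", "QualityScore", "SpatialAttention",
           "SelfAttention", "AggregationHead", "QualityModel", "build_variant",
           "apply_mask", "downsample_mask", "bce_loss"]


@dataclass(frozen=True)
class ModelSpec:
    """Configuration selecting a variant and its capacity.

    threshold is the probability cut for the 0/1 decision (default 0.5).
    """

    variant: str = "BL+SpatialAtt+MS"
    backbone: str = "resnet50"
    rescale_channels: tuple = (16, 32, 64)
    sir_out_channels: int = 128
    hidden: int = 128
    threshold: float = 0.5
    seed: int = 0

    def scaled(self) -> "ModelSpec":
        """Spec with capacity scaled down to match a reduced backbone."""
        if self.backbone != "reduced":
            return self
        return ModelSpec(self.variant, "reduced", (4, 8, 16), 32, 32,
                         self.threshold, self.seed)


@dataclass
class QualityScore:
    """Per-sample prediction: raw logit, probability, thresholded label."""

    logit: np.ndarray
    probability: np.ndarray
    label: np.ndarray


class SpatialAttention(nn.Module):
    """Several conv-BN-ReLU stacks ending in a 1-channel sigmoid map.

    Default: three 3x3 conv-BN-ReLU blocks narrowing the channels, then a
    1x1 conv to one channel squashed to [0,1].  The map is broadcast across
    channels when it multiplies the feature.
    """

    def __init__(self, cin: int, widths=(128, 64, 32), *, rng):
        super().__init__()
        chain = []
        c = cin
        for w in widths:
            chain.append(nn.ConvBNReLU(c, w, kernel=3, padding=1, rng=rng))
            c = w
        self.blocks = nn.Sequential(*chain)
        self.final = nn.Conv2d(c, 1, 1, rng=rng)

    def forward(self, feature: Tensor) -> Tensor:
        return self.final(self.blocks(feature)).sigmoid()


class SelfAttention(nn.Module):
    """Non-local block: scaled dot-product attention over spatial positions.

    Query/key are C/8-dim 1x1 projections, value is a C-dim 1x1 projection;
    attention weights softmax over key positions; the attended value passes
    through an output 1x1 projection and is added residually to the input.
    The two switches (`uniform_attention`, `residual`) exist so closed-form
    behavior can be exercised; both default to the trained configuration.
    """

    def __init__(self, cin: int, *, rng, qk_channels: int | None = None):
        super().__init__()
        self.qk = qk_channels or max(cin // 8, 1)
        self.query = nn.Conv2d(cin, self.qk, 1, bias=False, rng=rng)
        self.key = nn.Conv2d(cin, self.qk, 1, bias=False, rng=rng)
        self.value = nn.Conv2d(cin, cin, 1, bias=False, rng=rng)
        self.out = nn.Conv2d(cin, cin, 1, bias=False, rng=rng)
        self.residual = True
        self.uniform_attention = False
        self._last_attention: np.ndarray | None = None

    def attention_weights(self, feature: Tensor) -> Tensor:
        b, c, h, w = feature.shape
        n = h * w
        q = self.query(feature).reshape(b, self.qk, n).transpose(0, 2, 1)
        k = self.key(feature).reshape(b, self.qk, n)
        scores = (q @ k) * (1.0 / np.sqrt(self.qk))
        return scores.softmax(axis=-1)          # (B, N_query, N_key)

    def forward(self, feature: Tensor) -> Tensor:
        b, c, h, w = feature.shape
        n = h * w
        if self.uniform_attention:
            attn = Tensor(np.full((b, n, n), 1.0 / n, dtype=np.float32))
        else:
            attn = self.attention_weights(feature)
        self._last_attention = attn.data
        v = self.value(feature).reshape(b, c, n)
        attended = v @ attn.transpose(0, 2, 1)   # (B, C, N_query)
        attended = attended.reshape(b, c, h, w)
        y = self.out(attended)
        return feature + y if self.residual else y


class AggregationHead(nn.Module):
    """GAP followed by a fully-connected stack to a scalar logit."""

    def __init__(self, cin: int, hidden: int = 128, *, rng):
        super().__init__()
        self.fc1 = nn.Linear(cin, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, 1, rng=rng)

    def forward(self, feature: Tensor) -> Tensor:
        pooled = F.global_avg_pool(feature)
        return self.fc2(self.fc1(pooled).relu()).reshape(-1)


def downsample_mask(mask: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Area-average the binary eye mask to the feature grid, binarize at 0.5."""
    h, w = mask.shape
    if h % target_h or w % target_w:
        raise ValueError(f"mask {mask.shape} not divisible to ({target_h},{target_w})")
    fh, fw = h // target_h, w // target_w
    area = mask.astype(np.float32).reshape(target_h, fh, target_w, fw).mean(axis=(1, 3))
    return (area > 0.5).astype(np.float32)


def apply_mask(feature: Tensor, mask: np.ndarray) -> Tensor:
    """Gate a (B,C,h,w) feature elementwise by the eye-area mask.

    `mask` is (h, w) shared across the batch or (B, h, w) per sample, at
    image resolution (area-downsampled and binarized at 0.5) or already at
    the feature grid.
    """
    h, w = feature.shape[2], feature.shape[3]
    mask = np.asarray(mask)
    if mask.ndim == 3:
        if mask.shape[1:] != (h, w):
            mask = np.stack([downsample_mask(m, h, w) for m in mask])
        return feature * Tensor(mask.reshape(mask.shape[0], 1, h, w))
    if mask.shape != (h, w):
        mask = downsample_mask(mask, h, w)
    return feature * Tensor(mask.reshape(1, 1, h, w))


def bce_loss(logits: Tensor | np.ndarray, labels) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against binary labels."""
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    return F.bce_with_logits(logits, np.asarray(labels, dtype=np.float32))


class QualityModel(nn.Module):
    """A wired variant mapping image batches to quality scores."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        if spec.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {spec.variant!r}; valid names: {', '.join(VARIANTS)}")
        spec = spec.scaled()
        self.spec = spec
        self.variant = spec.variant
        rng = np.random.default_rng(spec.seed + 17)
        self.uses_sir = spec.variant.endswith("+MS")
        self.uses_mask = spec.variant == "BL+MASK"
        self.extractor = SIRExtractor(
            spec.backbone, spec.rescale_channels, spec.sir_out_channels,
            seed=spec.seed)
        if self.uses_sir:
            feat_ch = self.extractor.feature_channels
        else:
            feat_ch = self.extractor.backbone.config.stage_channels[3]
        self.attention = None
        if "SpatialAtt" in spec.variant:
            self.attention = SpatialAttention(feat_ch, rng=rng)
        elif "SelfAtt" in spec.variant:
            self.attention = SelfAttention(feat_ch, rng=rng)
        self.head = AggregationHead(feat_ch, spec.hidden, rng=rng)
        self._last_feature: Tensor | None = None
        self._last_attention_map: np.ndarray | None = None

    # -- feature extraction ----------------------------------------------

    def features(self, batch: Tensor) -> Tensor:
        if self.uses_sir:
            return self.extractor(batch)
        return self.extractor.backbone(batch)[3]

    def forward(self, batch: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """Scalar logit per sample; `mask` only consulted by BL+MASK."""
        feat = self.features(batch)
        self._last_feature = feat
        self._last_attention_map = None
        if self.uses_mask:
            if mask is None:
                raise ValueError("BL+MASK requires an eye-area mask")
            feat = apply_mask(feat, mask)
        elif isinstance(self.attention, SpatialAttention):
            amap = self.attention(feat)
            self._last_attention_map = amap.data[:, 0]
            feat = feat * amap
        elif isinstance(self.attention, SelfAttention):
            feat = self.attention(feat)
            attn = self.attention._last_attention
            if attn is not None:
                h, w = feat.shape[2], feat.shape[3]
                # saliency: how much each position is attended, averaged
                # over queries
                self._last_attention_map = attn.mean(axis=1).reshape(-1, h, w)
        return self.head(feat)

    def predict(self, batch: Tensor, mask: np.ndarray | None = None) -> QualityScore:
        with nn.no_grad():
            logit = self.forward(batch, mask=mask).data
        prob = 1.0 / (1.0 + np.exp(-logit))
        label = (prob > self.spec.threshold).astype(np.int64)
        return QualityScore(logit=logit, probability=prob, label=label)

    def parameter_groups(self):
        """(backbone params, newly-added params) for the 1:10 lr split."""
        bb = self.extractor.backbone.parameters()
        bb_ids = {id(p) for p in bb}
        new = [p for p in self.parameters() if id(p) not in bb_ids]
        return bb, new


def build_variant(spec: ModelSpec | str, **overrides) -> QualityModel:
    """Construct one of the five named variants.

    Accepts a ModelSpec or a variant name plus keyword overrides.
    """
    if isinstance(spec, str):
        spec = ModelSpec(variant=spec, **overrides)
    return QualityModel(spec)
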