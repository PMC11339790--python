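"""Saliency heat maps showing which regions drive the quality prediction.

For variants with a learned attention module the attention map itself is
visualized; for the plain baseline variants a gradient-weighted activation
map of the stage-4 feature is used instead (channel weights are the
gradients of the logit pooled spatially; the weighted sum is rectified).
Either way the coarse map is upsampled bilinearly to the image size,
min-max normalized to [0,1], and restricted to the eye area.  A good image
activates evenly across the retina; a defective region is left dark.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
from skimage import transform

from .model import QualityModel
from .nn import Tensor
from .preprocess import compute_eye_mask

__all__ = ["HeatMap", "attention_heatmap"]

OVERLAY_ALPHA = 0.4
COLORMAP = "jet"


@dataclass
class HeatMap:
    """Normalized saliency map plus a colorized blend with the image."""

    map: np.ndarray      # (S, S) in [0,1]
    overlay: np.ndarray  # (S, S, 3) in [0,1]


def _gradcam_map(model: QualityModel, batch: Tensor,
                 mask: np.ndarray | None) -> np.ndarray:
    """Gradient-weighted stage-4 activation map for attention-free variants."""
    model.eval()
    feat = model.extractor.backbone(batch)[3]
    feat.retain_grad()
    x = feat
    if model.uses_mask:
        from .model import apply_mask
        x = apply_mask(x, mask)
    logit = model.head(x).sum()
    logit.backward()
    weights = feat.grad.mean(axis=(2, 3), keepdims=True)
    cam = np.maximum((weights * feat.data).sum(axis=1), 0.0)
    return cam  # (B, h, w)


def _normalize(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    if hi - lo < 1e-12:
        return np.full_like(m, 0.5)  # all-constant map -> uniform 0.5
    return (m - lo) / (hi - lo)


def attention_heatmap(model: QualityModel, image: np.ndarray,
                      mask: np.ndarray | None = None) -> HeatMap:
    """Saliency heat map for one canonical (S, S, 3) image.

    `mask` is the eye-area map; computed from the image when omitted.
    Deterministic in eval mode and independent of batch packing.
    """
    s = image.shape[0]
    if image.shape != (s, s, 3):
        raise ValueError(f"expected a square SxSx3 image, got {image.shape}")
    if mask is None:
        mask = compute_eye_mask(image)
    batch = Tensor(image.transpose(2, 0, 1)[None])
    model.eval()
    if model.attention is not None:
        model.predict(batch, mask=mask)
        raw = model._last_attention_map[0]
    else:
        raw = _gradcam_map(model, batch, mask)[0]
    up = transform.resize(raw.astype(np.float64), (s, s), order=1,
                          preserve_range=True)
    norm = _normalize(up) * mask
    cmap = matplotlib.colormaps[COLORMAP]
    colored = cmap(norm)[..., :3]
    overlay = np.clip((1 - OVERLAY_ALPHA) * image + OVERLAY_ALPHA * colored, 0, 1)
    return HeatMap(map=norm.astype(np.float32), overlay=overlay.astype(np.float32))
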