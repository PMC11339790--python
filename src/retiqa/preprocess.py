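"""Image canonicalization: blank cropping, resizing, eye mask, noise.

Raw fundus photographs arrive at arbitrary aspect ratios with black
borders around the circular retina.  The pipeline crops the blank frame to
a square around the content, rescales to a square side divisible by 32
(default 512), derives a binary eye-area mask from brightness and edge
information, and — for robustness experiments — corrupts images with
additive Gaussian white noise.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, transform

__all__ = ["EmptyContentError", "crop_blank_to_square", "resize_canonical",
           "compute_eye_mask", "corrupt_gaussian", "canonicalize"]

BLANK_THRESHOLD = 0.02  # mean-channel brightness at or below this is "blank"


class EmptyContentError(ValueError):
    """Raised when an image holds no above-threshold content."""


def _validate_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{name} must be HxWx3, got {img.shape}")
    if img.shape[0] < 32 or img.shape[1] < 32:
        raise ValueError(f"{name} must be at least 32x32, got {img.shape[:2]}")
    if not np.isfinite(img).all() or img.min() < 0 or img.max() > 1:
        raise ValueError(f"{name} values must be finite and within [0,1]")
    return img


def crop_blank_to_square(img: np.ndarray,
                         brightness_threshold: float = BLANK_THRESHOLD) -> np.ndarray:
    """Tightest square crop around above-threshold content, centered on it.

    Content is any pixel whose mean-channel brightness exceeds
    `brightness_threshold`.  The square hull of the content bounding box is
    taken; when the box is non-square and the square would overrun the
    frame, the image is zero-padded symmetrically rather than cutting
    content.  Idempotent: a second application is the identity.
    """
    img = _validate_image(img)
    bright = img.mean(axis=2) > brightness_threshold
    if not bright.any():
        raise EmptyContentError("empty content: no pixel above brightness threshold")
    rows = np.flatnonzero(bright.any(axis=1))
    cols = np.flatnonzero(bright.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    side = max(r1 - r0, c1 - c0)

    def expand(lo, hi, limit):
        """Grow [lo,hi) to `side`, centered, clamped to [0,limit); return
        also the padding needed when the frame is too small."""
        extra = side - (hi - lo)
        lo2 = lo - extra // 2
        hi2 = lo2 + side
        pad_lo = max(0, -lo2)
        pad_hi = max(0, hi2 - limit)
        return max(lo2, 0), min(hi2, limit), pad_lo, pad_hi

    r0e, r1e, pr0, pr1 = expand(r0, r1, img.shape[0])
    c0e, c1e, pc0, pc1 = expand(c0, c1, img.shape[1])
    out = img[r0e:r1e, c0e:c1e]
    if pr0 or pr1 or pc0 or pc1:
        out = np.pad(out, ((pr0, pr1), (pc0, pc1), (0, 0)))
    assert out.shape[0] == out.shape[1] == side
    return out


def resize_canonical(img: np.ndarray, side: int = 512) -> np.ndarray:
    """Rescale a square image to (side, side, 3), side divisible by 32.

    Bilinear, antialiased when shrinking; values stay in [0,1].
    """
    img = _validate_image(img)
    if img.shape[0] != img.shape[1]:
        raise ValueError(f"expected a square image, got {img.shape[:2]}")
    if side % 32:
        raise ValueError(f"side must be divisible by 32, got {side}")
    if img.shape[0] == side:
        return img.copy()
    out = transform.resize(img, (side, side), order=1,
                           anti_aliasing=img.shape[0] > side,
                           preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def compute_eye_mask(img: np.ndarray) -> np.ndarray:
    """Binary eye-area map from brightness and edge information.

    Otsu-thresholded brightness is unioned with a dilated gradient-edge
    map, the largest connected component is kept, and holes are filled.
    Returns a (S, S) uint8 array with 1 inside the eye area.
    """
    img = _validate_image(img)
    if img.shape[0] != img.shape[1]:
        raise ValueError("eye mask expects a canonical (square) image")
    brightness = img.mean(axis=2)
    if brightness.max() <= BLANK_THRESHOLD:
        raise EmptyContentError("no eye area: image is entirely dark")
    thr = filters.threshold_otsu(brightness)
    fg = brightness > thr
    edges = filters.sobel(brightness)
    edge_thr = filters.threshold_otsu(edges) if edges.max() > 0 else np.inf
    fg |= morphology.dilation(edges > edge_thr, morphology.disk(2))
    if not fg.any():
        raise EmptyContentError("no eye area: empty foreground")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    # erode by the edge-dilation radius so the boundary stays tight
    eroded = morphology.erosion(fg, morphology.disk(2))
    if eroded.any():
        fg = ndimage.binary_fill_holes(eroded)
    return fg.astype(np.uint8)


def corrupt_gaussian(img: np.ndarray, mean: float = 0.0, var: float = 0.05,
                     seed: int | None = None) -> np.ndarray:
    """Additive Gaussian white noise on the [0,1] scale, then clipped.

    Defaults (mean 0, variance 0.05) match the robustness protocol used
    for the noise experiments.  Reproducible under a fixed seed.
    """
    img = _validate_image(img)
    if var < 0:
        raise ValueError(f"variance must be nonnegative, got {var}")
    if var == 0 and mean == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(mean, np.sqrt(var), size=img.shape).astype(np.float32)
    return np.clip(img + noise, 0.0, 1.0)


def canonicalize(img: np.ndarray, side: int = 512,
                 brightness_threshold: float = BLANK_THRESHOLD) -> np.ndarray:
    """crop_blank_to_square followed by resize_canonical."""
    return resize_canonical(crop_blank_to_square(img, brightness_threshold), side)


# --- PNG/JPEG plumbing ---------------------------------------------------

def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG as HxWx3 float32 in [0,1] (alpha dropped)."""
    from PIL import Image
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float32)
    return arr / 255.0


def save_image(path, img: np.ndarray, alpha: np.ndarray | None = None) -> None:
    """Write [0,1] RGB as 8-bit PNG, optionally with a binary alpha channel."""
    from PIL import Image
    arr = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    if alpha is not None:
        a = (np.clip(alpha, 0, 1) * 255).round().astype(np.uint8)
        arr = np.dstack([arr, a])
        Image.fromarray(arr, mode="RGBA").save(path)
    else:
        Image.fromarray(arr).save(path)


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a single-channel 8-bit PNG."""
    from PIL import Image
    Image.fromarray((mask > 0).astype(np.uint8) * 255, mode="L").save(path)
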