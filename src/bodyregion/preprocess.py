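"""Image-level preprocessing chain feeding the slice classifier.

Four deterministic steps per image, in order:

1. clip pixel values to ``[mean − 4σ, mean + 4σ]`` (per-image statistics);
2. normalize with ``(x − mean) / (2σ)``, so the mean maps to 0, mean ± 2σ to
   ±1 and the clip bounds to ±2 — the chain output therefore lies in [−2, 2];
3. copy the single grayscale channel to three identical channels;
4. resize with preserved aspect ratio (bilinear, longer side → 224) and
   zero-pad, centered, to 224 × 224.

Normalization precedes padding so a pad value of exactly 0 codes for the image
mean.  Constant images (σ = 0) carry no signal and map to all-zero output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

TARGET_SIZE = 224


@dataclass(frozen=True)
class ImageStats:
    """Per-image pixel mean and standard deviation (population σ)."""

    mean: float
    std: float

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("std must be >= 0")


def compute_stats(pixels: np.ndarray) -> ImageStats:
    arr = np.asarray(pixels, dtype=np.float64)
    return ImageStats(mean=float(arr.mean()), std=float(arr.std()))


def clip_intensities(pixels: np.ndarray, stats: ImageStats) -> np.ndarray:
    """Clip to [mean − 4σ, mean + 4σ]; values inside the interval unchanged."""
    if stats.std == 0:
        return np.asarray(pixels, dtype=np.float64).copy()
    lo, hi = stats.mean - 4 * stats.std, stats.mean + 4 * stats.std
    return np.clip(np.asarray(pixels, dtype=np.float64), lo, hi)


def normalize(pixels: np.ndarray, stats: ImageStats) -> np.ndarray:
    """Center/scale with (x − mean)/(2σ); σ = 0 maps to all zeros."""
    arr = np.asarray(pixels, dtype=np.float64)
    if stats.std == 0:
        return np.zeros_like(arr)
    return (arr - stats.mean) / (2.0 * stats.std)


def to_three_channel(pixels: np.ndarray) -> np.ndarray:
    """Stack a single-channel image into three identical channels (H, W, 3)."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"expected single-channel 2D image, got shape {arr.shape}")
    return np.repeat(arr[:, :, None], 3, axis=2)


def pad_resize(pixels: np.ndarray, target: int = TARGET_SIZE) -> np.ndarray:
    """Aspect-preserving bilinear resize (longer side → target) with centered zero padding.

    Accepts (H, W) or (H, W, 3) input and returns a (target, target, 3) float32
    array; padded margins are exactly 0.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim == 2:
        arr = to_three_channel(arr)
    h, w = arr.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("zero-area image")
    scale = target / max(h, w)
    new_h = max(1, round(h * scale))
    new_w = max(1, round(w * scale))
    if (new_h, new_w) != (h, w):
        # channels are identical by construction; resample one and copy
        resized = np.asarray(
            Image.fromarray(arr[:, :, 0].astype(np.float32), mode="F").resize(
                (new_w, new_h), Image.BILINEAR
            )
        )
        arr = np.repeat(resized[:, :, None], 3, axis=2)
    out = np.zeros((target, target, 3), dtype=np.float32)
    top = (target - arr.shape[0]) // 2
    left = (target - arr.shape[1]) // 2
    out[top : top + arr.shape[0], left : left + arr.shape[1], :] = arr
    return out


def preprocess_image(pixels: np.ndarray, target: int = TARGET_SIZE) -> np.ndarray:
    """Full chain: clip → normalize → three channels → pad/resize.

    Deterministic; output is (target, target, 3) float32 with values in
    [−2, 2] and zero padding.
    """
    stats = compute_stats(pixels)
    x = clip_intensities(pixels, stats)
    x = normalize(x, stats)
    return pad_resize(x, target=target)
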