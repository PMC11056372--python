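"""Dermoscopy image pre-processing.

The chain mirrors a classical dermoscopy cleanup pipeline: hair removal by
morphological closing along oriented lines (a DullRazor-style filter), colour
to grayscale conversion, contrast enhancement, and a median/Gaussian/Lee
smoothing bank.  Every stage is individually callable; ``preprocess_pipeline``
applies them in a fixed, configurable order.

Images are plain numpy arrays: RGB images are ``(H, W, 3) uint8``, grayscale
images ``(H, W) uint8``.  All stages preserve shape and the 8-bit range.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.morphology import disk, dilation

__all__ = [
    "PreprocessConfig",
    "PipelineStageError",
    "remove_hair",
    "negative",
    "to_grayscale",
    "median_filter",
    "gaussian_filter",
    "lee_filter",
    "enhance_contrast",
    "preprocess_pipeline",
]

logger = logging.getLogger("dermoscan.preprocess")

# ITU-R BT.601 luma weights (the classical video/matrix-lab convention)
_LUMA = np.array([0.299, 0.587, 0.114])


class PipelineStageError(RuntimeError):
    """A pre-processing stage failed; the message names the stage."""


def _check_rgb(image: np.ndarray) -> None:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixels, got {image.dtype}")
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("image has a zero dimension")


def _check_gray(image: np.ndarray) -> None:
    if image.ndim != 2:
        raise ValueError(f"expected an (H, W) grayscale image, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixels, got {image.dtype}")
    if image.size == 0:
        raise ValueError("image is empty")


def _line_footprints(length: int) -> list[np.ndarray]:
    """Flat line structuring elements at 0, 45, 90 and 135 degrees."""
    horiz = np.ones((1, length), dtype=bool)
    vert = np.ones((length, 1), dtype=bool)
    diag = np.eye(length, dtype=bool)
    anti = np.fliplr(diag)
    return [horiz, vert, diag, anti]


def remove_hair(
    image: np.ndarray,
    kernel_length: int = 9,
    threshold: int = 25,
    min_hair_size: int = 12,
) -> np.ndarray:
    """DullRazor-style hair removal.

    Per channel: the image is lightly median-smoothed (3x3) to suppress pixel
    noise, then closed with line structuring elements at 0/45/90/135 degrees
    (grayscale closing brightens thin dark structures).  Pixels where the
    orientation-maximal closing exceeds the smoothed image by more than
    ``threshold`` gray levels form the hair mask; tiny components (residual
    noise hits) are discarded, the mask is dilated by 1 px, and masked pixels
    are replaced by the closing estimate of the underlying skin.  The
    threshold sits well below the hair/skin contrast (~100+ gray levels) but
    above closing excursions of plain skin/lesion texture noise.
    """
    _check_rgb(image)
    if kernel_length < 3:
        raise ValueError(f"kernel_length must be >= 3, got {kernel_length}")
    fps = _line_footprints(kernel_length)
    hair = np.zeros(image.shape[:2], dtype=bool)
    closed = np.empty_like(image)
    for c in range(3):
        ch = ndi.median_filter(image[..., c], size=3, mode="nearest")
        closings = np.stack([ndi.grey_closing(ch, footprint=fp) for fp in fps])
        cmax = closings.max(axis=0)
        hair |= (cmax.astype(int) - ch.astype(int)) > threshold
        closed[..., c] = cmax
    labels = measure.label(hair)
    if labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= min_hair_size)
        hair = np.isin(labels, keep[keep > 0])
    hair = dilation(hair, disk(1))
    out = image.copy()
    out[hair] = closed[hair]
    return out


def negative(image: np.ndarray) -> np.ndarray:
    """Image negative relative to the image maximum: out = max(x) - x."""
    _check_gray(image)
    return (int(image.max()) - image.astype(int)).astype(np.uint8)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance conversion with BT.601 weights, rounded to 8 bits."""
    _check_rgb(image)
    gray = image.astype(float) @ _LUMA
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with replicate-border padding; window must be odd."""
    _check_gray(image)
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    return ndi.median_filter(image, size=window, mode="nearest")


def gaussian_filter(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Convolution with a normalized Gaussian kernel (replicate borders)."""
    _check_gray(image)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    out = ndi.gaussian_filter(image.astype(float), sigma, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def lee_filter(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Lee adaptive local-statistics filter.

    out = mean + k*(in - mean) with k = var/(var + noise_var), where the
    per-pixel mean/variance come from the local window and the noise variance
    is estimated as the mean of the local variances.  Flat regions (k -> 0)
    are smoothed to the mean; strong edges (k -> 1) pass through.
    """
    _check_gray(image)
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    x = image.astype(float)
    mean = ndi.uniform_filter(x, window, mode="nearest")
    sqmean = ndi.uniform_filter(x * x, window, mode="nearest")
    var = np.maximum(sqmean - mean * mean, 0.0)
    noise_var = float(var.mean())
    if noise_var == 0.0:
        return image.copy()
    k = var / (var + noise_var)
    out = mean + k * (x - mean)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def enhance_contrast(image: np.ndarray, clip: float = 0.01) -> np.ndarray:
    """Percentile-clipped linear contrast stretch to the full 8-bit range.

    ``clip`` is the total histogram-tail fraction discarded (clip/2 on each
    side) before stretching; a constant image is returned unchanged.  The
    mapping is monotone in the input ordering.
    """
    _check_gray(image)
    if not (0 < clip <= 1):
        raise ValueError(f"clip must be in (0, 1], got {clip}")
    lo = float(np.percentile(image, 50.0 * clip))
    hi = float(np.percentile(image, 100.0 - 50.0 * clip))
    if hi <= lo:
        return image.copy()
    out = (image.astype(float) - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


@dataclass
class PreprocessConfig:
    """Free parameters of the pre-processing chain (all stages exposed)."""

    hair_kernel_length: int = 9
    hair_threshold: int = 25
    median_window: int = 3
    gaussian_sigma: float = 1.0
    lee_window: int = 5
    contrast_clip: float = 0.01
    apply_negative: bool = False
    apply_hair_removal: bool = True

    def __post_init__(self) -> None:
        for name in ("median_window", "lee_window"):
            w = getattr(self, name)
            if w % 2 == 0 or w < 3:
                raise ValueError(f"{name} must be odd and >= 3, got {w}")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if not (0 < self.contrast_clip <= 1):
            raise ValueError("contrast_clip must be in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def preprocess_pipeline(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Apply the full chain: hair removal -> grayscale -> contrast -> median ->
    Gaussian -> Lee -> (optional) negative.

    Returns the smoothed grayscale image.  Stage failures are re-raised as
    :class:`PipelineStageError` naming the stage.
    """
    cfg = config or PreprocessConfig()
    stages: list[tuple[str, callable]] = []
    if cfg.apply_hair_removal:
        stages.append(
            ("remove_hair", lambda im: remove_hair(im, cfg.hair_kernel_length, cfg.hair_threshold))
        )
    stages += [
        ("to_grayscale", to_grayscale),
        ("enhance_contrast", lambda im: enhance_contrast(im, cfg.contrast_clip)),
        ("median_filter", lambda im: median_filter(im, cfg.median_window)),
        ("gaussian_filter", lambda im: gaussian_filter(im, cfg.gaussian_sigma)),
        ("lee_filter", lambda im: lee_filter(im, cfg.lee_window)),
    ]
    if cfg.apply_negative:
        stages.append(("negative", negative))
    out = image
    for name, fn in stages:
        try:
            out = fn(out)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc
        logger.debug("stage %s done (shape %s)", name, out.shape)
    return out
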