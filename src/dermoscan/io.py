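"""PNG image / mask reading and writing (thin wrappers over Pillow)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["load_image", "load_mask", "save_image", "save_mask"]


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel mask file as an (H, W) boolean array (>127 is on)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 127


def save_image(image: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image).save(path)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit {0, 255} PNG."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask.astype(np.uint8) * 255).save(path)
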