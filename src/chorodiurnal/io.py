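"""Reading and writing en-face images and cohort tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from chorodiurnal.quantify import EnFaceImage

__all__ = ["load_enface_image", "save_enface_image", "load_mask", "save_mask"]


def load_enface_image(
    path: str | Path,
    scan_width_mm: float,
    layer: str,
    fovea_center_px: tuple[float, float] | None = None,
) -> EnFaceImage:
    """Load a single-channel TIFF or PNG en-face image."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path))
    if pixels.ndim == 3:  # collapse an RGB export to one channel
        pixels = pixels[..., 0]
    return EnFaceImage(
        pixels=pixels.astype(float),
        scan_width_mm=scan_width_mm,
        layer=layer,
        fovea_center_px=fovea_center_px,
        metadata={"source": str(path)},
    )


def save_enface_image(image: EnFaceImage, path: str | Path) -> None:
    """Write pixels as 8-bit single-channel TIFF or PNG."""
    path = Path(path)
    arr = np.clip(np.asarray(image.pixels, dtype=float), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask (nonzero = masked) from TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)
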