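"""Image I/O: 8-bit grayscale PNG/TIFF in, object crops and overlays out."""
from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .segmentation import ChromosomeObject, MetaphaseImage

__all__ = ["read_image", "write_image", "write_object_png", "write_overlay_png"]

#: ITU-R 601 luminance weights for RGB inputs
_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path: str | Path, true_dose_gy: float | None = None) -> MetaphaseImage:
    """Read a PNG/TIFF micrograph as 8-bit grayscale (RGB converted by
    luminance, 16-bit rescaled)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.dtype == np.uint16:
        arr = arr / 257.0
    arr = np.clip(np.asarray(arr, dtype=float), 0, 255).astype(np.uint8)
    return MetaphaseImage(pixels=arr, image_id=Path(path).stem, true_dose_gy=true_dose_gy)


def write_image(path: str | Path, image: MetaphaseImage) -> None:
    iio.imwrite(path, image.pixels)


def write_object_png(path: str | Path, obj: ChromosomeObject) -> None:
    """Crop of the object's gray values on white background."""
    crop = np.full(obj.mask.shape, 255, dtype=np.uint8)
    crop[obj.mask] = obj.gray_crop[obj.mask]
    iio.imwrite(path, crop)


def write_overlay_png(path: str | Path, obj: ChromosomeObject, centerline) -> None:
    """Debug overlay: the crop with the centerline burned in (RGB)."""
    crop = np.full(obj.mask.shape, 255, dtype=np.uint8)
    crop[obj.mask] = obj.gray_crop[obj.mask]
    rgb = np.stack([crop] * 3, axis=-1)
    for r, c in np.round(centerline.points).astype(int):
        if 0 <= r < rgb.shape[0] and 0 <= c < rgb.shape[1]:
            rgb[r, c] = (255, 0, 0)
    iio.imwrite(path, rgb)
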