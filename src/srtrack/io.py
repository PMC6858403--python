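"""Frame and mask IO: PNG/TIFF single images, stacks and numbered directories."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["read_frame", "read_frames", "write_frame", "read_mask", "write_mask"]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


def to_gray01(img: np.ndarray) -> np.ndarray:
    """Convert a raster image to float intensities in [0, 1] (luma for RGB)."""
    img = np.asarray(img)
    if img.ndim == 3:
        rgb = img[..., :3].astype(float)
        img = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    img = img.astype(float)
    if img.max() > 1.0:
        img = img / (65535.0 if img.max() > 255 else 255.0)
    return np.clip(img, 0.0, 1.0)


def read_frame(path: str | Path) -> np.ndarray:
    return to_gray01(iio.imread(Path(path)))


def read_frames(path: str | Path) -> list[np.ndarray]:
    """Read a directory of numbered frames or a multi-page TIFF stack."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no image files in {path}")
        return [read_frame(p) for p in files]
    if path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            return [to_gray01(stack)]
        return [to_gray01(s) for s in stack]
    return [read_frame(path)]


def write_frame(path: str | Path, frame: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frame.astype(np.float32))
    else:
        iio.imwrite(path, (np.clip(frame, 0, 1) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > (img.max() / 2 if img.max() > 1 else 0)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))
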