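"""Raster scene container and plain-raster I/O.

A :class:`RasterScene` is the single image container every pipeline stage
consumes: a float array of intensities on a canonical [0, 1] scale, either
single-band (grayscale) or 3-band (RGB), plus the ground resolution in
metres per pixel.  Scenes are read and written as 8-bit PNG or as TIFF with
the ground resolution stored in the image metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
import tifffile

__all__ = [
    "RasterScene",
    "read_scene",
    "write_scene",
    "read_mask_png",
    "write_mask_png",
]


@dataclass(frozen=True)
class RasterScene:
    """An aerial image with known ground resolution.

    Parameters
    ----------
    pixels
        Array of shape (rows, cols) or (rows, cols, 3) with intensities
        in [0, 1].
    resolution_m
        Ground sampling distance, metres per pixel (> 0).
    """

    pixels: np.ndarray
    resolution_m: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(
                f"pixels must be (rows, cols) or (rows, cols, 3), got {px.shape}"
            )
        if px.size == 0:
            raise ValueError("scene must contain at least one pixel")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if not self.resolution_m > 0:
            raise ValueError("resolution_m must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def intensity(self) -> np.ndarray:
        """Single-band intensity: multi-channel scenes collapse to the
        per-pixel mean, so one rule set applies to gray and RGB imagery."""
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels.mean(axis=2)

    @property
    def extent_m(self) -> tuple[float, float]:
        """Ground extent (height_m, width_m) of the scene."""
        r, c = self.shape
        return r * self.resolution_m, c * self.resolution_m


def _to_uint8(values: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(values * 255.0), 0, 255).astype(np.uint8)


def write_scene(scene: RasterScene, path: str | Path) -> Path:
    """Write a scene as 8-bit PNG (.png) or TIFF (.tif/.tiff).

    TIFF output records the ground resolution both as a JSON image
    description and as the TIFF resolution tag (pixels per centimetre),
    so the scene round-trips with its geometry.  PNG carries the
    resolution in a tEXt chunk.
    """
    path = Path(path)
    data = _to_uint8(scene.pixels)
    if path.suffix.lower() == ".png":
        img = Image.fromarray(data)
        from PIL.PngImagePlugin import PngInfo

        meta = PngInfo()
        meta.add_text("resolution_m", repr(scene.resolution_m))
        img.save(path, pnginfo=meta)
    elif path.suffix.lower() in (".tif", ".tiff"):
        px_per_cm = 1.0 / (scene.resolution_m * 100.0)
        tifffile.imwrite(
            path,
            data,
            description=json.dumps({"resolution_m": scene.resolution_m}),
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
        )
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")
    return path


def read_scene(path: str | Path, resolution_m: float | None = None) -> RasterScene:
    """Read a PNG or TIFF scene.

    The ground resolution is taken from the file metadata when present;
    an explicit ``resolution_m`` overrides it and is required when the
    file carries none.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        img = Image.open(path)
        data = np.asarray(img, dtype=np.float64) / 255.0
        meta_res = img.text.get("resolution_m") if hasattr(img, "text") else None
        file_res = float(meta_res) if meta_res is not None else None
    elif path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray().astype(np.float64) / 255.0
            file_res = None
            desc = page.tags.get("ImageDescription")
            if desc is not None:
                try:
                    file_res = float(json.loads(desc.value)["resolution_m"])
                except (ValueError, KeyError, TypeError):
                    file_res = None
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")
    res = resolution_m if resolution_m is not None else file_res
    if res is None:
        raise ValueError(f"{path} carries no ground resolution; pass resolution_m")
    if data.ndim == 3 and data.shape[2] == 4:  # drop alpha if present
        data = data[:, :, :3]
    return RasterScene(pixels=data, resolution_m=res)


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as a bit-exact 0/255 single-band PNG."""
    path = Path(path)
    arr = (np.asarray(mask).astype(bool).astype(np.uint8)) * 255
    Image.fromarray(arr).save(path)
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG mask back to a boolean array."""
    data = np.asarray(Image.open(path))
    if data.ndim == 3:
        data = data[..., 0]
    return data > 127
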