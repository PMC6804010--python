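"""Calibrated chemical images and the image standardization chain.

A :class:`ChemImage` holds one secondary-ion (or fragment) channel of one
sample as an 8-bit intensity grid with a physical pixel size.  The
standardization chain mirrors common ToF-SIMS export practice: exported
three-channel (RGB) rasters are reduced to a single channel by per-pixel
summation and the summed range [0, 765] is linearly rescaled back to
[0, 255]; summation happens in widened integers so densitometry is not
destroyed by premature clipping.

Coordinate convention: row-major grids, origin at the top-left pixel,
0-based indices.  The physical coordinate of pixel ``(r, c)`` is its
center, ``((c + 0.5) * pixel_size_um, (r + 0.5) * pixel_size_um)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from .exceptions import BitDepthError

__all__ = ["ChemImage", "read_image", "write_image", "sum_channels", "area_um2"]

_POLARITIES = ("positive", "negative")


@dataclass
class ChemImage:
    """One ion/fragment channel of one sample, calibrated in µm/pixel."""

    data: np.ndarray
    pixel_size_um: float
    channel: str = ""
    polarity: str = "positive"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"expected a 2-D intensity grid, got shape {self.data.shape}")
        if self.data.dtype != np.uint8:
            arr = self.data
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie within [0, 255]")
            self.data = arr.astype(np.uint8)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def field_size_um(self) -> tuple[float, float]:
        """Physical (height, width) of the imaged field in µm."""
        return (self.shape[0] * self.pixel_size_um, self.shape[1] * self.pixel_size_um)

    @property
    def field_area_um2(self) -> float:
        h, w = self.field_size_um
        return h * w

    def with_data(self, data: np.ndarray) -> "ChemImage":
        return replace(self, data=data)


def sum_channels(rgb: np.ndarray) -> np.ndarray:
    """Collapse a three-channel raster to one 8-bit channel.

    Per-pixel sum of the three channels in widened integers, then a linear
    rescale of the summed range [0, 765] into [0, 255] with round-half-up.
    Invariant under permutation of the input channels.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) raster, got shape {rgb.shape}")
    s = rgb.astype(np.int64).sum(axis=-1)
    # exact integer round-half-up of s * 255 / 765 == s / 3
    out = (s * 510 + 765) // 1530
    return out.astype(np.uint8)


def read_image(
    path: str | Path,
    pixel_size_um: float,
    channel: str = "",
    polarity: str = "positive",
    sample_id: str = "",
) -> ChemImage:
    """Read an 8-bit grayscale or RGB raster (TIFF/PNG) as a ChemImage.

    RGB inputs are channel-summed and rescaled (see :func:`sum_channels`);
    rasters deeper than 8 bits per channel are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.dtype != np.uint8:
        raise BitDepthError(
            f"{path.name}: expected 8-bit raster, got dtype {arr.dtype}"
        )
    if arr.ndim == 3:
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        arr = sum_channels(arr)
    elif arr.ndim != 2:
        raise ValueError(f"{path.name}: not a 2-D raster (shape {arr.shape})")
    return ChemImage(arr, pixel_size_um, channel=channel, polarity=polarity, sample_id=sample_id)


def write_image(img: ChemImage, path: str | Path, sidecar: bool = True) -> Path:
    """Write an 8-bit grayscale TIFF/PNG plus a YAML metadata sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, img.data)
    else:
        Image.fromarray(img.data, mode="L").save(path)
    if sidecar:
        meta = {
            "pixel_size_um": float(img.pixel_size_um),
            "channel": img.channel,
            "polarity": img.polarity,
            "sample_id": img.sample_id,
        }
        path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))
    return path


def read_sidecar(path: str | Path) -> dict:
    """Read the YAML sidecar written next to an image file."""
    path = Path(path)
    return yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())


def area_um2(img: ChemImage, pixel_count: int) -> float:
    """Physical area of ``pixel_count`` pixels in µm²."""
    if pixel_count < 0:
        raise ValueError("pixel_count must be non-negative")
    return float(pixel_count) * img.pixel_size_um**2
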