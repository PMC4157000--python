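"""Grayscale image I/O, cropping and unit conversion.

All pipeline stages exchange :class:`GrayImage`: a 2-D float64 array of
intensities normalized to [0, 1] together with the physical sampling
density in pixels per millimetre.  The coordinate convention is
``(row, col)``, 0-based, with the row index increasing with tissue depth
and the column index running laterally along the vessel.

8-bit (or 16-bit) raster files are only touched at the edges of the
pipeline; everything in between is floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ValidationError

#: Pixel density of the reference acquisition protocol (pixels per mm).
DEFAULT_PIXEL_DENSITY = 16.66


@dataclass(frozen=True)
class GrayImage:
    """A grayscale image with physical scale metadata.

    Parameters
    ----------
    pixels
        2-D float array with values in ``[0, 1]``; rows index depth,
        columns index the lateral direction.
    pixel_density
        Sampling density in pixels per millimetre (> 0).
    """

    pixels: np.ndarray
    pixel_density: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValidationError(f"pixels must be 2-D, got ndim={px.ndim}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValidationError(f"image too small: shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValidationError("pixels contain non-finite values")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValidationError(
                f"intensities outside [0, 1]: range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))
        if not self.pixel_density > 0:
            raise ValidationError(f"pixel_density must be > 0, got {self.pixel_density}")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CropWindow:
    """Half-open, 0-based crop rectangle ``[row_start, row_end) x [col_start, col_end)``."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise ValidationError(f"bad row range [{self.row_start}, {self.row_end})")
        if not (0 <= self.col_start < self.col_end):
            raise ValidationError(f"bad col range [{self.col_start}, {self.col_end})")

    def validate_against(self, img: GrayImage) -> None:
        if self.row_end > img.n_rows or self.col_end > img.n_cols:
            raise ValidationError(
                f"crop window {self} exceeds image of shape {img.shape}"
            )


#: Crop used for the reference 768x576 scanner frames: strips the textual
#: overlay and keeps a 401x401 region around the vessel.
DEFAULT_CROP = CropWindow(99, 500, 199, 600)


def load_image(path: str | Path, pixel_density: float = DEFAULT_PIXEL_DENSITY) -> GrayImage:
    """Read a PNG/TIFF raster file as a normalized grayscale image.

    Integer images are rescaled linearly so the maximum representable
    value maps to 1.0 (255 for 8-bit, 65535 for 16-bit).  Color images
    are converted by averaging the channels.
    """
    arr = iio.imread(Path(path))
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValidationError(f"zero-size image: {path}")
    if np.issubdtype(arr.dtype, np.integer):
        px = arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    elif arr.dtype == bool:
        px = arr.astype(np.float64)
    else:
        px = np.clip(arr.astype(np.float64), 0.0, 1.0)
    if px.ndim == 3:  # color -> channel average (after dtype normalization)
        px = px[..., :3].mean(axis=2)
    if px.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality {px.ndim}: {path}")
    return GrayImage(px, pixel_density)


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` as an 8-bit grayscale raster file."""
    quantized = np.rint(img.pixels * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), quantized)


def crop_image(img: GrayImage, window: CropWindow) -> GrayImage:
    """Extract a sub-image; pixel density is preserved."""
    window.validate_against(img)
    sub = img.pixels[window.row_start : window.row_end, window.col_start : window.col_end]
    return GrayImage(sub.copy(), img.pixel_density)


def mm_to_px(mm: float, image_or_density: GrayImage | float) -> float:
    """Convert a physical length in mm to a (possibly fractional) pixel count.

    No rounding is applied here; callers round according to their own
    documented rule.
    """
    if mm < 0:
        raise ValidationError(f"length must be >= 0 mm, got {mm}")
    density = (
        image_or_density.pixel_density
        if isinstance(image_or_density, GrayImage)
        else float(image_or_density)
    )
    if not density > 0:
        raise ValidationError(f"pixel density must be > 0, got {density}")
    return mm * density


def px_to_mm(px: float, image_or_density: GrayImage | float) -> float:
    """Convert a pixel count to millimetres."""
    density = (
        image_or_density.pixel_density
        if isinstance(image_or_density, GrayImage)
        else float(image_or_density)
    )
    if not density > 0:
        raise ValidationError(f"pixel density must be > 0, got {density}")
    return px / density


def write_results_table(records: list[dict], path: str | Path) -> pd.DataFrame:
    """Write per-image measurement results as a CSV table.

    One row per image: path, status, mean IMT in mm, and the min/max
    per-column boundary distance in mm.  Returns the written frame.
    """
    columns = ["path", "status", "mean_imt_mm", "min_mm", "max_mm", "failure_reason"]
    frame = pd.DataFrame.from_records(records)
    for col in columns:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame[columns]
    frame.to_csv(Path(path), index=False)
    return frame
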