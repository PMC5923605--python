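"""Calibrated grayscale micrographs: containers and TIFF/PNG + JSON I/O.

An :class:`ImageCalibration` ties a pixel grid to physical scan dimensions;
the area of one pixel follows from the scan area divided over the pixel
grid, which is what converts a segmented pixel count into a physical
particle-occupied area.  An :class:`SEMImage` is an integer intensity grid
plus its calibration and bit depth.

Images are written as TIFF (or PNG) with the calibration in a JSON sidecar
next to the image (``<stem>.calibration.json``), so a directory of images is
self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from . import units

__all__ = [
    "ImageCalibration",
    "SEMImage",
    "write_image",
    "read_image",
]


@dataclass(frozen=True)
class ImageCalibration:
    """Physical scan dimensions (nm) and pixel counts of a micrograph.

    Per-axis pixel pitches may differ (non-square pixels are supported);
    pixel_area is the exact product of the two pitches.
    """

    scan_width_nm: float
    scan_height_nm: float
    pixels_x: int
    pixels_y: int

    def __post_init__(self) -> None:
        for field in ("scan_width_nm", "scan_height_nm", "pixels_x", "pixels_y"):
            value = getattr(self, field)
            if not value > 0:
                raise ValueError(f"{field} must be > 0, got {value!r}")

    @property
    def pixel_width_nm(self) -> float:
        return self.scan_width_nm / self.pixels_x

    @property
    def pixel_height_nm(self) -> float:
        return self.scan_height_nm / self.pixels_y

    @property
    def pixel_area_nm2(self) -> float:
        return self.pixel_width_nm * self.pixel_height_nm

    @property
    def pixel_area_um2(self) -> float:
        return units.nm2_to_um2(self.pixel_area_nm2)

    @property
    def field_area_um2(self) -> float:
        return units.nm2_to_um2(self.scan_width_nm * self.scan_height_nm)

    @property
    def field_area_cm2(self) -> float:
        return units.um2_to_cm2(self.field_area_um2)

    def to_dict(self) -> dict:
        return {
            "scan_width_nm": self.scan_width_nm,
            "scan_height_nm": self.scan_height_nm,
            "pixels_x": self.pixels_x,
            "pixels_y": self.pixels_y,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ImageCalibration":
        return cls(
            scan_width_nm=float(data["scan_width_nm"]),
            scan_height_nm=float(data["scan_height_nm"]),
            pixels_x=int(data["pixels_x"]),
            pixels_y=int(data["pixels_y"]),
        )


@dataclass(frozen=True)
class SEMImage:
    """A grayscale micrograph: integer intensities + calibration + bit depth.

    ``intensities`` has shape (pixels_y, pixels_x); values must lie within
    [0, 2**bit_depth - 1].
    """

    intensities: np.ndarray
    bit_depth: int
    calibration: ImageCalibration

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth!r}")
        arr = np.asarray(self.intensities)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"intensities must be integer-typed, got {arr.dtype}")
        expected = (self.calibration.pixels_y, self.calibration.pixels_x)
        if arr.shape != expected:
            raise ValueError(
                f"intensity grid shape {arr.shape} does not match calibration "
                f"(pixels_y, pixels_x) = {expected}"
            )
        if arr.size and (arr.min() < 0 or arr.max() > self.max_intensity):
            raise ValueError(
                f"intensities out of [0, {self.max_intensity}] for {self.bit_depth}-bit image"
            )

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix("").with_suffix(".calibration.json")


def write_image(image: SEMImage, path: str | Path) -> Path:
    """Write a micrograph as TIFF or PNG plus a calibration JSON sidecar."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    data = np.asarray(image.intensities, dtype=dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}; use .tif or .png")
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps({"bit_depth": image.bit_depth, **image.calibration.to_dict()}, indent=2)
    )
    return sidecar


def read_image(path: str | Path, calibration: ImageCalibration | None = None) -> SEMImage:
    """Read a TIFF/PNG micrograph; calibration from the sidecar unless given."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 3:  # RGB(A) PNG: collapse identical channels to grayscale
        data = data[..., 0]
    bit_depth = 16 if data.dtype.itemsize > 1 else 8
    if calibration is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no calibration given and sidecar {sidecar} not found for {path}"
            )
        meta = json.loads(sidecar.read_text())
        bit_depth = int(meta.get("bit_depth", bit_depth))
        calibration = ImageCalibration.from_dict(meta)
    return SEMImage(intensities=data, bit_depth=bit_depth, calibration=calibration)
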