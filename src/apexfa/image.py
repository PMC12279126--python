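"""Radiograph container and image I/O.

A radiograph is a 2-D grayscale pixel array with a physical pixel spacing
(mm/pixel).  Spacing is carried in a JSON sidecar for PNG/TIFF files and read
from the PixelSpacing / ImagerPixelSpacing tags for DICOM files.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class Radiograph:
    """2-D grayscale radiograph with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray
        2-D array of gray levels (float or integer).  Values are expected on
        (or rescaled to) the 0-255 scale used by 8-bit periapical sensors.
    spacing : float
        Pixel spacing in mm/pixel (isotropic).
    id : str
        Patient / image identifier.
    """

    pixels: np.ndarray
    spacing: float
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("radiograph pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("radiograph pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("radiograph pixels must be non-negative")
        if not (self.spacing > 0):
            raise ValueError("pixel spacing must be positive (mm/pixel)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_8bit(self) -> "Radiograph":
        """Return a copy rescaled to the 0-255 gray-level scale.

        Images already within [0, 255] are passed through unchanged so that
        8-bit inputs keep their native scale (on which the Canny 35/50
        thresholds are defined); deeper bit depths are rescaled linearly.
        """
        px = self.pixels
        if px.max() > 255:
            lo, hi = float(px.min()), float(px.max())
            px = (px - lo) / (hi - lo) * 255.0
        return Radiograph(px, self.spacing, self.id)


def write_radiograph(path: str | Path, image: Radiograph) -> None:
    """Write a radiograph as PNG or TIFF with a JSON spacing sidecar."""
    path = Path(path)
    arr = np.clip(np.round(image.pixels), 0, 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"spacing_mm": image.spacing, "id": image.id}) + "\n"
    )


def read_radiograph(path: str | Path, spacing: float | None = None) -> Radiograph:
    """Read a radiograph from PNG, TIFF or DICOM.

    For PNG/TIFF, spacing is taken from the ``<file>.json`` sidecar unless
    given explicitly.  For DICOM, the PixelSpacing (falling back to
    ImagerPixelSpacing) tag is honored.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom"}:
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        if spacing is None:
            tag = getattr(ds, "PixelSpacing", None) or getattr(
                ds, "ImagerPixelSpacing", None
            )
            if tag is None:
                raise ValueError(f"{path}: DICOM carries no pixel-spacing tag")
            spacing = float(tag[0])
        return Radiograph(arr, spacing, id=path.stem).to_8bit()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path).astype(float)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("I")).astype(float)
    if spacing is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(f"{path}: no spacing given and no JSON sidecar found")
        meta = json.loads(sidecar.read_text())
        spacing = float(meta["spacing_mm"])
    return Radiograph(arr, spacing, id=path.stem).to_8bit()
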