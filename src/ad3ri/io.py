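"""Image and mask I/O, the analysis channel, and the macular region of interest.

All modules share one coordinate convention: (row, col), 0-based, pixel centres
at integer coordinates.  Intensities are carried as floats (nominally 0-255);
quantization to 8-bit happens only on export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RetinalImage",
    "GradingMask",
    "load_image",
    "roi_mask",
    "write_mask",
    "read_mask",
]


@dataclass
class RetinalImage:
    """A single-channel fundus intensity grid with physical metadata.

    Parameters
    ----------
    pixels
        2-D float array of intensities, nominally on the 0-255 scale.
    resolution_um
        Spatial sampling in µm per pixel (isotropic), > 0.
    roi_center
        (row, col) of the macula centre.  The analysis region of interest is
        the disc of ``roi_diameter_um`` around this point; every downstream
        stage operates on ROI pixels only.
    roi_diameter_um
        Diameter of the macular region of interest in µm (Wisconsin grading
        convention: 3000 µm disc around the macula).
    """

    pixels: np.ndarray
    resolution_um: float
    roi_center: tuple[float, float]
    roi_diameter_um: float = 3000.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not self.resolution_um > 0:
            raise ValueError(f"resolution_um must be > 0, got {self.resolution_um}")
        self.roi_center = (float(self.roi_center[0]), float(self.roi_center[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "RetinalImage":
        """Copy of this image with ``pixels`` replaced, metadata preserved."""
        return RetinalImage(
            pixels=np.asarray(pixels, dtype=float),
            resolution_um=self.resolution_um,
            roi_center=self.roi_center,
            roi_diameter_um=self.roi_diameter_um,
        )


@dataclass
class GradingMask:
    """Binary drusen/background raster tied to a RetinalImage geometry."""

    pixels: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        uniq = np.unique(self.pixels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be strictly binary (0/1)")
        self.pixels = self.pixels.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_mm2(self, resolution_um: float) -> float:
        """Marked area in mm² given the image resolution."""
        return float(self.pixels.sum()) * (resolution_um / 1000.0) ** 2


def load_image(
    path: str | Path,
    resolution_um: float,
    roi_center: tuple[float, float],
    roi_diameter_um: float = 3000.0,
) -> RetinalImage:
    """Read a PNG/TIFF/BMP fundus photograph and extract the analysis channel.

    For RGB input the green channel is used: it shows the best drusen
    contrast and the least sensitivity to illumination abnormalities.
    Grayscale input is taken as-is.
    """
    if resolution_um is None or roi_center is None:
        raise ValueError("resolution_um and roi_center are required metadata")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises backend-specific types
        raise IOError(f"cannot read image {path!r}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            raise IOError(f"expected 3 channels for colour input, got {arr.shape[2]}")
        chan = arr[:, :, 1]
    elif arr.ndim == 2:
        chan = arr
    else:
        raise IOError(f"unsupported image dimensionality {arr.ndim}")
    return RetinalImage(
        pixels=chan.astype(float),
        resolution_um=float(resolution_um),
        roi_center=roi_center,
        roi_diameter_um=float(roi_diameter_um),
    )


def roi_mask(img: RetinalImage) -> np.ndarray:
    """Boolean grid of pixels whose centre lies within the macular ROI disc.

    Membership is Euclidean distance in µm from the macula centre, strictly
    geometric — invariant under any intensity change.
    """
    rows, cols = img.shape
    radius_um = img.roi_diameter_um / 2.0
    rr, cc = np.ogrid[:rows, :cols]
    d2 = (rr - img.roi_center[0]) ** 2 + (cc - img.roi_center[1]) ** 2
    mask = d2 * img.resolution_um**2 <= radius_um**2
    if img.roi_diameter_um > 0 and not mask.any():
        raise ValueError("region of interest lies entirely outside the image")
    return mask


def write_mask(path: str | Path, mask: GradingMask) -> None:
    """Write a binary mask as an 8-bit PNG (0 = background, 255 = drusen)."""
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255), extension=".png")


def read_mask(path: str | Path, source: str = "file") -> GradingMask:
    """Read a mask written by :func:`write_mask` (any nonzero pixel is drusen)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return GradingMask(pixels=(arr > 0).astype(np.uint8), source=source)
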