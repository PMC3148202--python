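"""Global contrast normalization against a vessel-based RMS reference.

After illumination flattening, image contrast still varies between
photographs.  Retinal vessels are always present and darker than the
background, so the contrast between vessels and background serves as a
per-image reference: a square window of 250 µm (about twice a main vessel
diameter) slides over the ROI, the 51 darkest windows (by mean intensity) are
selected — these typically contain a single vessel over uniform background —
and the overall RMS contrast is the median of their per-window RMS contrast.

Intensities are then remapped affinely so that the overall RMS contrast
becomes the reference value 15 and the background sits at the constant grey
level A = 85, keeping two thirds of the 0-255 scale for bright (drusen)
structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RetinalImage, roi_mask

__all__ = ["ContrastEstimate", "estimate_rmsc", "normalize_contrast"]

RMSC_REFERENCE = 15.0
BACKGROUND_LEVEL = 85.0


@dataclass
class ContrastEstimate:
    """Vessel-window RMS contrast summary for one image.

    ``rmsc_overall`` is the median of the per-window standard deviations of
    the ``n_windows`` darkest windows; ``selected_window`` is the top-left
    (row, col) of the window realising that median, and may be manually
    relocated when the automatic selection lands on an image defect.
    """

    rmsc_overall: float
    window_um: float
    n_windows: int
    selected_window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.rmsc_overall < 0:
            raise ValueError("rmsc_overall must be >= 0")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")


def _window_side(window_um: float, resolution_um: float) -> int:
    side = int(round(window_um / resolution_um))
    if side < 2:
        raise ValueError(
            f"contrast window of {window_um} µm spans {side} pixel(s) at "
            f"{resolution_um} µm/pixel; need at least 2"
        )
    return side


def estimate_rmsc(
    img: RetinalImage,
    window_um: float = 250.0,
    n: int = 51,
    window_override: tuple[int, int] | None = None,
) -> ContrastEstimate:
    """Measure the overall RMS contrast from the darkest ROI windows.

    The window slides with a stride of half its side and is a candidate only
    when it lies entirely inside the ROI disc.  Windows are ranked by mean
    intensity ascending; ``rmsc_overall`` is the median standard deviation of
    the ``n`` darkest.  ``window_override`` forces the measurement window to a
    given top-left corner instead (manual relocation).
    """
    side = _window_side(window_um, img.resolution_um)
    roi = roi_mask(img)
    px = img.pixels

    if window_override is not None:
        r, c = window_override
        block = px[r : r + side, c : c + side]
        if block.shape != (side, side):
            raise ValueError("override window falls outside the image")
        return ContrastEstimate(float(np.std(block)), window_um, 1, (int(r), int(c)))

    stride = max(1, side // 2)
    rows, cols = px.shape
    stats: list[tuple[float, float, int, int]] = []  # (mean, sd, r, c)
    for r in range(0, rows - side + 1, stride):
        for c in range(0, cols - side + 1, stride):
            if not roi[r : r + side, c : c + side].all():
                continue
            block = px[r : r + side, c : c + side]
            stats.append((float(np.mean(block)), float(np.std(block)), r, c))
    if len(stats) < n:
        raise ValueError(
            f"only {len(stats)} candidate windows inside the ROI; {n} required"
        )
    stats.sort(key=lambda t: t[0])
    darkest = stats[:n]
    sds = np.array([t[1] for t in darkest])
    order = np.argsort(sds, kind="stable")
    median_idx = order[(n - 1) // 2]  # window realising the (lower) median sd
    rmsc = float(np.median(sds))
    _, _, mr, mc = darkest[median_idx]
    return ContrastEstimate(rmsc, window_um, n, (mr, mc))


def normalize_contrast(
    img: RetinalImage,
    est: ContrastEstimate,
    rmsc_reference: float = RMSC_REFERENCE,
    background: float = BACKGROUND_LEVEL,
) -> RetinalImage:
    """Affinely remap intensities to the reference contrast and background.

    I' = (I - b) * (rmsc_reference / rmsc_overall) + background, with b the
    median ROI intensity (the background level: background pixels dominate the
    ROI).  Output is clipped to [0, 255].
    """
    if not est.rmsc_overall > 0:
        raise ValueError("cannot normalize a flat image (rmsc_overall = 0)")
    roi = roi_mask(img)
    b = float(np.median(img.pixels[roi]))
    gain = rmsc_reference / est.rmsc_overall
    out = (img.pixels - b) * gain + background
    return img.with_pixels(np.clip(out, 0.0, 255.0))
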