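"""Drusen area quantification from the analytic image model.

Drusen contours are the super-level set of the rendered model at a threshold
expressed as a fraction above the normalized background (18% by default, the
accuracy optimum of the threshold calibration sweep).  A classical global
threshold applied directly to the normalized image (30% above background) is
provided as the comparison baseline; being applied to the raw pixels it
counts noise excursions the model suppresses, hence its over-detection bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .contrast import BACKGROUND_LEVEL
from .evaluate import pixel_confusion
from .io import GradingMask, RetinalImage, roi_mask
from .modelling import DrusenModel

__all__ = [
    "DrusenReport",
    "model_to_mask",
    "drusen_report",
    "global_threshold_baseline",
    "threshold_sweep",
]

QUANTIFICATION_THRESHOLD = 0.18
BASELINE_THRESHOLD = 0.30


@dataclass
class DrusenReport:
    """Per-image drusen indicators derived from the analytic model."""

    mask: GradingMask
    n_spots: int
    total_area_mm2: float
    mean_spot_area_mm2: float
    confluence_count: int

    def to_dict(self) -> dict:
        return {
            "n_spots": self.n_spots,
            "total_area_mm2": self.total_area_mm2,
            "mean_spot_area_mm2": self.mean_spot_area_mm2,
            "confluence_count": self.confluence_count,
        }


def model_to_mask(
    model: DrusenModel,
    shape: tuple[int, int],
    threshold_frac: float = QUANTIFICATION_THRESHOLD,
    roi: np.ndarray | None = None,
) -> GradingMask:
    """Threshold the rendered model at background*(1 + threshold_frac)."""
    if not 0 <= threshold_frac <= 1:
        raise ValueError("threshold_frac must be in [0, 1]")
    render = model.render(shape)
    level = model.background * (1.0 + threshold_frac)
    mask = render >= level
    if roi is not None:
        mask &= roi
    return GradingMask(pixels=mask.astype(np.uint8), source="AD3RI")


def drusen_report(
    model: DrusenModel,
    img: RetinalImage,
    threshold_frac: float = QUANTIFICATION_THRESHOLD,
) -> DrusenReport:
    """Mask, spot count, areas and confluence for one image.

    A fitted component counts as a spot when its own peak clears the
    threshold (A >= background * threshold_frac); spots whose centres share a
    connected mask component are confluent.
    """
    roi = roi_mask(img)
    mask = model_to_mask(model, img.shape, threshold_frac, roi)
    level_margin = model.background * threshold_frac
    spots = [g for g in model.gaussians if g.A >= level_margin]
    comp, _ = ndimage.label(mask.pixels, structure=np.ones((3, 3), dtype=int))
    per_comp: dict[int, int] = {}
    for g in spots:
        r = int(round(g.y0))
        c = int(round(g.x0))
        if 0 <= r < comp.shape[0] and 0 <= c < comp.shape[1] and comp[r, c] > 0:
            per_comp[comp[r, c]] = per_comp.get(comp[r, c], 0) + 1
    confluence = sum(1 for v in per_comp.values() if v > 1)
    total = mask.area_mm2(img.resolution_um)
    n_spots = len(spots)
    return DrusenReport(
        mask=mask,
        n_spots=n_spots,
        total_area_mm2=total,
        mean_spot_area_mm2=total / n_spots if n_spots else 0.0,
        confluence_count=confluence,
    )


def global_threshold_baseline(
    norm_img: RetinalImage,
    threshold_frac: float = BASELINE_THRESHOLD,
    background: float = BACKGROUND_LEVEL,
) -> GradingMask:
    """Classical global threshold on the normalized image (baseline method)."""
    roi = roi_mask(norm_img)
    mask = (norm_img.pixels >= background * (1.0 + threshold_frac)) & roi
    return GradingMask(pixels=mask.astype(np.uint8), source="THRESH")


def threshold_sweep(
    models: list[DrusenModel],
    truths: list[GradingMask],
    rois: list[np.ndarray] | None = None,
    thresholds: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """Pixel agreement of the model masks against truth across thresholds.

    For every threshold fraction the model masks of all images are pooled
    against their truth masks and sensitivity, specificity and Cohen's kappa
    are computed over the pooled confusion counts.  Returns the table and the
    argmax-kappa threshold — the calibration that fixes the quantification
    threshold.
    """
    if not models or len(models) != len(truths):
        raise ValueError("need equal, non-empty model and truth lists")
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 0.5001, 0.01), 4)
    if rois is None:
        rois = [None] * len(models)
    rows = []
    for t in thresholds:
        tp = fp = fn = tn = 0
        for model, truth, roi in zip(models, truths, rois):
            mask = model_to_mask(model, truth.shape, float(t), roi)
            sel = roi if roi is not None else np.ones(truth.shape, dtype=bool)
            a = mask.pixels[sel]
            b = truth.pixels[sel]
            tp += int(np.sum(a & b))
            fp += int(np.sum(a & ~b))
            fn += int(np.sum(~a & b))
            tn += int(np.sum(~a & ~b))
        sens, spec, kappa = _confusion_stats(tp, fp, fn, tn)
        rows.append(
            {"threshold": float(t), "sensitivity": sens, "specificity": spec,
             "kappa": kappa}
        )
    table = pd.DataFrame(rows)
    best = float(table.loc[table["kappa"].idxmax(), "threshold"])
    return table, best


def _confusion_stats(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float]:
    from .evaluate import confusion_metrics

    return confusion_metrics(tp, fp, fn, tn)
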