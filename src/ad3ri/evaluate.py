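"""Grader-agreement statistics for drusen masks and areas.

Agreement is assessed both globally, on per-image total affected areas
(coefficient of variation, intraclass correlation), and locally, pixel to
pixel (sensitivity, specificity, Cohen's kappa).  The ground truth for a set
of expert gradings is their consensus (majority vote per pixel), and images
whose expert area CV exceeds 50% are flagged as outliers and excluded from
summary statistics — low-contrast images on which graders fundamentally
disagree carry no usable reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GradingMask

__all__ = [
    "AgreementReport",
    "area_cv",
    "icc_agreement",
    "confusion_metrics",
    "pixel_confusion",
    "consensus_truth",
    "outlier_filter",
    "compare_to_truth",
    "expert_vs_experts",
]

OUTLIER_CV_PERCENT = 50.0


@dataclass
class AgreementReport:
    """Summary agreement of one grader (or method) against a ground truth."""

    cv_percent: float
    icc: float
    sensitivity: float
    specificity: float
    kappa: float
    per_image: pd.DataFrame = field(default_factory=pd.DataFrame)
    outliers: list = field(default_factory=list)


def area_cv(areas) -> float:
    """Coefficient of variation of a set of area measurements, in percent.

    100 * sample standard deviation / mean.  Scale-invariant; undefined for a
    non-positive mean (e.g. a control image on which most graders marked
    nothing).
    """
    a = np.asarray(areas, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two measurements")
    mean = a.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean area")
    return float(100.0 * a.std(ddof=1) / mean)


def icc_agreement(area_table) -> float:
    """Intraclass correlation of an images x raters area grid.

    Two-way random effects, absolute agreement, single measure (ICC2) — the
    standard form for method-vs-reference area agreement.  Identical columns
    are a degenerate perfect-agreement case and return 1.0.
    """
    table = np.asarray(area_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an (images >= 2) x (raters >= 2) table")
    if np.allclose(table, table[:, [0]]):
        return 1.0
    n, k = table.shape
    long = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": table.ravel(),
        }
    )
    import pingouin as pg  # deferred: heavy import

    res = pg.intraclass_corr(
        data=long, targets="targets", raters="raters", ratings="ratings"
    )
    # absolute-agreement single-measure row; the label differs across
    # pingouin versions ("ICC2" vs "ICC(A,1)")
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    return float(res.loc[sel, "ICC"].iloc[0])


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float]:
    """Sensitivity, specificity and Cohen's kappa from 2x2 counts."""
    total = tp + fp + fn + tn
    sens = tp / (tp + fn) if (tp + fn) else 1.0
    spec = tn / (tn + fp) if (tn + fp) else 1.0
    po = (tp + tn) / total
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / total**2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    return float(sens), float(spec), float(kappa)


def pixel_confusion(
    test: GradingMask, truth: GradingMask, roi: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Pixel-to-pixel sensitivity, specificity and kappa over the ROI."""
    if test.shape != truth.shape:
        raise ValueError(f"mask geometry mismatch: {test.shape} vs {truth.shape}")
    sel = roi if roi is not None else np.ones(test.shape, dtype=bool)
    if roi is not None and roi.shape != test.shape:
        raise ValueError("ROI geometry mismatch")
    a = test.pixels[sel]
    b = truth.pixels[sel]
    tp = int(np.sum(a & b))
    fp = int(np.sum(a & ~b))
    fn = int(np.sum(~a & b))
    tn = int(np.sum(~a & ~b))
    return confusion_metrics(tp, fp, fn, tn)


def consensus_truth(masks: list[GradingMask]) -> GradingMask:
    """Majority-vote consensus of expert masks (ties count as marked)."""
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("all masks must share one geometry")
    stack = np.stack([m.pixels for m in masks]).astype(float)
    return GradingMask(pixels=(stack.mean(axis=0) >= 0.5).astype(np.uint8),
                       source="truth")


def outlier_filter(
    per_image_expert_areas, image_ids=None, cv_limit: float = OUTLIER_CV_PERCENT
) -> tuple[list, list]:
    """Split image ids into retained and outliers by expert-area CV.

    An image is an outlier when the CV of its expert areas exceeds
    ``cv_limit`` percent (default 50): beyond that the experts effectively
    disagree on what is there.
    """
    table = np.asarray(per_image_expert_areas, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need an images x (>=2 experts) table")
    if image_ids is None:
        image_ids = list(range(1, table.shape[0] + 1))
    retained, outliers = [], []
    for iid, row in zip(image_ids, table):
        try:
            cv = area_cv(row)
        except ValueError:
            cv = np.inf  # no measurable consensus at all
        (outliers if cv > cv_limit else retained).append(iid)
    return retained, outliers


def _pair_cv(a: float, b: float) -> float:
    """CV of a two-measurement set (grader area vs reference area)."""
    m = (a + b) / 2.0
    if m <= 0:
        return np.nan
    return float(100.0 * abs(a - b) / np.sqrt(2.0) / m)


def compare_to_truth(
    test_masks: list[GradingMask],
    truth_masks: list[GradingMask],
    rois: list[np.ndarray] | None = None,
    resolution_um: float = 12.5,
    image_ids=None,
) -> AgreementReport:
    """Agreement of one grading series against per-image ground truths.

    Per image: pixel sensitivity/specificity/kappa over the ROI and the CV of
    the (grading area, truth area) pair.  Headline values average the
    per-image metrics; the ICC is computed on the two area columns.
    """
    if len(test_masks) != len(truth_masks) or not test_masks:
        raise ValueError("need equal, non-empty mask lists")
    if rois is None:
        rois = [None] * len(test_masks)
    if image_ids is None:
        image_ids = list(range(1, len(test_masks) + 1))
    rows = []
    for iid, test, truth, roi in zip(image_ids, test_masks, truth_masks, rois):
        sens, spec, kappa = pixel_confusion(test, truth, roi)
        at = test.area_mm2(resolution_um)
        ar = truth.area_mm2(resolution_um)
        rows.append(
            {"image": iid, "area_mm2": at, "truth_area_mm2": ar,
             "cv_percent": _pair_cv(at, ar), "sensitivity": sens,
             "specificity": spec, "kappa": kappa}
        )
    per_image = pd.DataFrame(rows)
    areas = per_image[["area_mm2", "truth_area_mm2"]].to_numpy()
    icc = icc_agreement(areas) if len(per_image) >= 2 else np.nan
    return AgreementReport(
        cv_percent=float(np.nanmean(per_image["cv_percent"])),
        icc=icc,
        sensitivity=float(per_image["sensitivity"].mean()),
        specificity=float(per_image["specificity"].mean()),
        kappa=float(per_image["kappa"].mean()),
        per_image=per_image,
    )


def expert_vs_experts(
    masks_per_image: list[list[GradingMask]],
    rois: list[np.ndarray] | None = None,
    resolution_um: float = 12.5,
) -> list[AgreementReport]:
    """Score each expert against the consensus of the remaining experts.

    ``masks_per_image[i][e]`` is expert e's mask for image i; every image must
    carry the same number (>= 3) of experts.  Expert e's report compares
    their masks with the leave-one-out consensus truths.
    """
    if not masks_per_image:
        raise ValueError("no images")
    n_experts = len(masks_per_image[0])
    if n_experts < 3:
        raise ValueError("need at least 3 experts for leave-one-out scoring")
    if any(len(row) != n_experts for row in masks_per_image):
        raise ValueError("every image needs the same expert set")
    reports = []
    for e in range(n_experts):
        own = [row[e] for row in masks_per_image]
        truths = [
            consensus_truth([m for j, m in enumerate(row) if j != e])
            for row in masks_per_image
        ]
        reports.append(compare_to_truth(own, truths, rois, resolution_um))
    return reports
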