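"""End-to-end drusen quantification: flatten, normalize, segment, model, quantify."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from . import contrast, gpl, illumination, modelling, quantify
from .config import PipelineConfig
from .gpl import LabelMap
from .io import RetinalImage, roi_mask
from .modelling import DrusenModel, FitConstraints
from .quantify import DrusenReport

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Every intermediate artifact of one pipeline run."""

    flattened: RetinalImage
    normalized: RetinalImage
    labels: LabelMap
    model: DrusenModel
    report: DrusenReport
    timings: dict[str, float] = field(default_factory=dict)


def run_pipeline(img: RetinalImage, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full chain on one image.  Deterministic given the config."""
    cfg = config or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    flattened, _ = illumination.correct_illumination(
        img,
        iterations=cfg.iterations,
        p=cfg.p,
        decimation=cfg.decimation,
        nominal_background=cfg.background,
    )
    timings["flatten"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    est = contrast.estimate_rmsc(
        flattened, cfg.window_um, cfg.n_windows, window_override=cfg.contrast_window
    )
    normalized = contrast.normalize_contrast(
        flattened, est, cfg.rmsc_reference, cfg.background
    )
    timings["normalize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    labels = gpl.segment(normalized.pixels, roi_mask(normalized), delta_a=cfg.delta_a)
    timings["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cons = FitConstraints(
        sigma_min=cfg.sigma_min,
        s_f_range=cfg.s_f_range,
        d_range=cfg.d_range,
        max_iterations=cfg.max_iterations,
    )
    model = modelling.build_model(
        normalized,
        labels,
        background=cfg.background,
        margin_frac=cfg.margin_frac,
        constraints=cons,
        free_baseline=cfg.free_baseline,
        min_component_px=cfg.min_component_px,
    )
    timings["model"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = quantify.drusen_report(model, normalized, cfg.threshold_frac)
    timings["quantify"] = time.perf_counter() - t0

    return PipelineResult(
        flattened=flattened,
        normalized=normalized,
        labels=labels,
        model=model,
        report=report,
        timings=timings,
    )
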