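"""Analytic drusen modelling with Modified Gaussian functions.

A druse in a normalized fundus image looks like a smooth intensity elevation,
well captured by an elliptical Gaussian generalised with a profile exponent:

    MG(x, y) = z0 + A * exp(-[ x'^2 / (2 sigma_x^2)
                             + y'^2 / (2 (sigma_x * s_F)^2) ]^d)

where (x', y') are the (col, row) offsets from the centre (x0, y0) rotated by
-theta.  The eight parameters are translation (x0, y0, z0), amplitude A,
rotation theta, x-width sigma_x, y/x width ratio s_F, and the exponent d that
morphs the profile between thin (d < 1), bell (d = 1) and square-ish (d > 1)
shapes.

The image is first cut into sections — connected regions 10% above the
normalized background, padded with surrounding background — and each section
is fitted independently by constrained least squares, one Modified Gaussian
per segmentation maximum, which keeps the joint fits small and convergent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .contrast import BACKGROUND_LEVEL
from .gpl import LabelMap
from .io import RetinalImage, roi_mask

__all__ = [
    "ModifiedGaussian",
    "Section",
    "DrusenModel",
    "FitConstraints",
    "evaluate_mg",
    "section_image",
    "fit_section",
    "build_model",
]


@dataclass
class ModifiedGaussian:
    """8-parameter analytic drusen primitive (pixel coordinates, x = col)."""

    x0: float
    y0: float
    z0: float
    A: float
    theta: float
    sigma_x: float
    s_F: float
    d: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.sigma_x <= 0 or self.s_F <= 0 or self.d <= 0:
            raise ValueError(
                "require A >= 0, sigma_x > 0, s_F > 0, d > 0; got "
                f"A={self.A}, sigma_x={self.sigma_x}, s_F={self.s_F}, d={self.d}"
            )
        self.theta = float(self.theta) % np.pi

    def __call__(self, row, col) -> np.ndarray:
        return evaluate_mg(self, row, col)

    def bump(self, row, col) -> np.ndarray:
        """Contribution above baseline: MG(row, col) - z0."""
        return evaluate_mg(self, row, col) - self.z0


def evaluate_mg(g: ModifiedGaussian, row, col):
    """Evaluate a Modified Gaussian at (row, col) grids or scalars."""
    dx = np.asarray(col, dtype=float) - g.x0
    dy = np.asarray(row, dtype=float) - g.y0
    ct, st = np.cos(g.theta), np.sin(g.theta)
    xp = ct * dx + st * dy  # rotate by -theta
    yp = -st * dx + ct * dy
    q = xp**2 / (2.0 * g.sigma_x**2) + yp**2 / (2.0 * (g.sigma_x * g.s_F) ** 2)
    return g.z0 + g.A * np.exp(-np.power(q, g.d))


@dataclass
class Section:
    """A cropped sub-image holding one isolated or confluent drusen group."""

    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    pixels: np.ndarray
    seeds: list[tuple[int, int, float]]  # (row, col, amplitude) in full-image coords


@dataclass
class FitConstraints:
    """Box constraints for the per-component fit parameters.

    Amplitude is bounded by the available grey range above background,
    sigma_x by the section extent; the shape factor and exponent boxes keep
    the optimiser away from degenerate needle/plateau solutions.
    """

    amplitude_max: float | None = None  # default: 255 - background
    sigma_min: float = 0.5
    s_f_range: tuple[float, float] = (0.2, 5.0)
    d_range: tuple[float, float] = (0.3, 3.0)
    max_iterations: int = 200
    tol: float = 1e-8


@dataclass
class DrusenModel:
    """Sum of Modified Gaussians over a flat background."""

    gaussians: list[ModifiedGaussian]
    background: float = BACKGROUND_LEVEL
    fit_rmse: list[float] = field(default_factory=list)
    flagged_sections: list[int] = field(default_factory=list)

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        """Model image: background plus every component's bump."""
        rr, cc = np.meshgrid(
            np.arange(shape[0], dtype=float),
            np.arange(shape[1], dtype=float),
            indexing="ij",
        )
        out = np.full(shape, float(self.background))
        for g in self.gaussians:
            out += g.bump(rr, cc)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "background": self.background,
                "fit_rmse": self.fit_rmse,
                "flagged_sections": self.flagged_sections,
                "gaussians": [asdict(g) for g in self.gaussians],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DrusenModel":
        obj = json.loads(text)
        return cls(
            gaussians=[ModifiedGaussian(**g) for g in obj["gaussians"]],
            background=obj["background"],
            fit_rmse=list(obj.get("fit_rmse", [])),
            flagged_sections=list(obj.get("flagged_sections", [])),
        )


def section_image(
    norm_img: RetinalImage,
    labels: LabelMap,
    background: float = BACKGROUND_LEVEL,
    margin_frac: float = 0.10,
    pad: int | None = None,
    min_component_px: int = 4,
) -> list[Section]:
    """Cut the normalized image into independent drusen sections.

    Pixels more than ``margin_frac`` above the normalized background are
    grouped into 8-connected components; each component's bounding box is
    padded with surrounding background (a quarter of its larger extent,
    clamped to [3, 10] pixels, unless ``pad`` is given) and the segmentation
    maxima falling inside the component become the section's seeds.
    Components below ``min_component_px`` pixels are discarded: even the
    smallest hard drusen (< 63 µm diameter) span several pixels at typical
    resolutions, so single-pixel excursions are noise, not deposits.
    """
    px = norm_img.pixels
    roi = roi_mask(norm_img)
    thresh = background * (1.0 + margin_frac)
    above = (px > thresh) & roi
    comp, n_comp = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    sections: list[Section] = []
    if n_comp == 0:
        return sections
    slices = ndimage.find_objects(comp)
    maxima = list(labels.maxima.values())
    sizes = ndimage.sum_labels(above, comp, index=np.arange(1, n_comp + 1))
    for i, sl in enumerate(slices, start=1):
        if sl is None or sizes[i - 1] < min_component_px:
            continue
        r0, r1 = sl[0].start, sl[0].stop
        c0, c1 = sl[1].start, sl[1].stop
        if pad is None:
            p = int(np.clip(round(max(r1 - r0, c1 - c0) / 4), 3, 10))
        else:
            p = pad
        r0p, c0p = max(0, r0 - p), max(0, c0 - p)
        r1p = min(px.shape[0], r1 + p)
        c1p = min(px.shape[1], c1 + p)
        seeds = [
            (r, c, amp)
            for (r, c, amp) in maxima
            if comp[r, c] == i  # maxima pixel inside this component
        ]
        if not seeds:
            # component without a recorded maximum: seed at its brightest pixel
            rr, cc = ndimage.maximum_position(px, labels=comp, index=i)
            seeds = [(int(rr), int(cc), float(px[rr, cc]))]
        sections.append(
            Section(
                bbox=(r0p, c0p, r1p, c1p),
                pixels=px[r0p:r1p, c0p:c1p].copy(),
                seeds=seeds,
            )
        )
    return sections


def _initial_sigma(sec: Section, background: float, margin_frac: float) -> float:
    """Width guess from the section's above-threshold footprint per seed."""
    above = sec.pixels > background * (1.0 + margin_frac)
    area = max(int(above.sum()), 1) / max(len(sec.seeds), 1)
    return max(1.0, np.sqrt(area / np.pi) / 1.6)


def fit_section(
    sec: Section,
    background: float = BACKGROUND_LEVEL,
    constraints: FitConstraints | None = None,
    free_baseline: bool = False,
    margin_frac: float = 0.10,
) -> tuple[list[ModifiedGaussian], float, bool]:
    """Jointly fit one Modified Gaussian per seed to a section.

    Components are initialised at their seed position with the seed amplitude
    above background, isotropic (s_F = 1), unrotated, bell-profiled (d = 1),
    and optimised simultaneously by constrained least squares (trust-region
    reflective) on the section pixels.  ``free_baseline`` lets each
    component's z0 float instead of pinning it to the shared background.

    Returns (gaussians in full-image coordinates, RMSE, flagged); a fit that
    fails to converge keeps its initial parameters and is flagged rather than
    raising.
    """
    if not sec.seeds:
        raise ValueError("section has no seeds")
    cons = constraints or FitConstraints()
    amp_max = cons.amplitude_max if cons.amplitude_max is not None else 255.0 - background
    r0, c0, r1, c1 = sec.bbox
    rr, cc = np.meshgrid(
        np.arange(r0, r1, dtype=float), np.arange(c0, c1, dtype=float), indexing="ij"
    )
    target = sec.pixels.astype(float)
    extent = float(max(r1 - r0, c1 - c0))
    sigma0 = min(_initial_sigma(sec, background, margin_frac), extent)

    per = 8 if free_baseline else 7
    x0, lb, ub = [], [], []
    for (sr, sc, amp) in sec.seeds:
        a0 = float(np.clip(amp - background, 1e-3, amp_max))
        x0 += [sc, sr, a0, 0.0, sigma0, 1.0, 1.0]
        lb += [c0 - 2.0, r0 - 2.0, 0.0, -np.pi, cons.sigma_min, *map(float, (cons.s_f_range[0], cons.d_range[0]))]
        ub += [c1 + 1.0, r1 + 1.0, amp_max, np.pi, extent, cons.s_f_range[1], cons.d_range[1]]
        if free_baseline:
            x0.append(background)
            lb.append(0.0)
            ub.append(255.0)
    x0, lb, ub = np.array(x0), np.array(lb), np.array(ub)
    x0 = np.clip(x0, lb, ub)

    def unpack(v: np.ndarray) -> list[ModifiedGaussian]:
        out = []
        for i in range(len(sec.seeds)):
            p = v[i * per : (i + 1) * per]
            z0 = p[7] if free_baseline else background
            out.append(
                ModifiedGaussian(
                    x0=p[0], y0=p[1], z0=float(z0), A=max(p[2], 0.0),
                    theta=p[3], sigma_x=max(p[4], cons.sigma_min * 0.5),
                    s_F=p[5], d=p[6],
                )
            )
        return out

    def residual(v: np.ndarray) -> np.ndarray:
        model = np.full(target.shape, float(background))
        for g in unpack(v):
            model += g.bump(rr, cc)
        return (model - target).ravel()

    flagged = False
    try:
        res = least_squares(
            residual,
            x0,
            bounds=(lb, ub),
            method="trf",
            xtol=cons.tol,
            ftol=cons.tol,
            gtol=cons.tol,
            max_nfev=cons.max_iterations * max(len(x0), 1),
        )
        ok = res.success
        params = res.x if ok else x0
        flagged = not ok
    except Exception:  # keep the pipeline alive on a pathological section
        params, flagged = x0, True
    gaussians = unpack(params)
    model = np.full(target.shape, float(background))
    for g in gaussians:
        model += g.bump(rr, cc)
    rmse = float(np.sqrt(np.mean((model - target) ** 2)))
    return gaussians, rmse, flagged


def build_model(
    norm_img: RetinalImage,
    labels: LabelMap,
    background: float = BACKGROUND_LEVEL,
    margin_frac: float = 0.10,
    constraints: FitConstraints | None = None,
    free_baseline: bool = False,
    min_component_px: int = 4,
) -> DrusenModel:
    """Section the image and fit every section; assemble the image model."""
    sections = section_image(
        norm_img, labels, background, margin_frac, min_component_px=min_component_px
    )
    gaussians: list[ModifiedGaussian] = []
    rmses: list[float] = []
    flagged: list[int] = []
    for i, sec in enumerate(sections):
        gs, rmse, bad = fit_section(
            sec, background, constraints, free_baseline, margin_frac
        )
        gaussians.extend(gs)
        rmses.append(rmse)
        if bad:
            flagged.append(i)
    return DrusenModel(
        gaussians=gaussians,
        background=background,
        fit_rmse=rmses,
        flagged_sections=flagged,
    )
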