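"""Fundus phantom generator with analytic ground truth.

Phantoms emulate the image properties the pipeline must cope with: a smooth
background around a reference grey level, a low-frequency multiplicative
illumination pattern, dark elongated vessels, bright drusen with
Modified-Gaussian profiles (isolated and confluent) and additive noise.
The drusen ground truth is derived analytically from the generating
parameters, so every stage of the pipeline can be validated at desk scale
without clinical data.

Defaults model an already well-exposed photograph: background at the nominal
grey level 85, vessels ~125 µm wide and deep enough that the darkest-window
RMS contrast sits near the reference contrast 15, drusen amplitudes 20-40
grey levels, additive noise sd 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .contrast import BACKGROUND_LEVEL
from .io import GradingMask, RetinalImage, roi_mask
from .modelling import ModifiedGaussian

__all__ = [
    "Vessel",
    "PhantomSpec",
    "default_phantom",
    "render_phantom",
    "analytic_drusen_area_px",
    "simulate_experts",
]

#: Vessel depth (grey levels) giving darkest-window RMS contrast near the
#: reference value 15 for the default geometry; see docs/methods.md.
DEFAULT_VESSEL_DEPTH = 42.2
DEFAULT_VESSEL_WIDTH_UM = 125.0


@dataclass
class Vessel:
    """Dark elongated structure: polyline track with Gaussian cross-section."""

    points: list[tuple[float, float]]  # (row, col) vertices
    width_um: float = DEFAULT_VESSEL_WIDTH_UM
    depth: float = DEFAULT_VESSEL_DEPTH  # intensity drop at the centreline


@dataclass
class PhantomSpec:
    """Full description of a synthetic fundus image.

    ``illumination_ratio`` is the peak-to-trough ratio of the multiplicative
    illumination field (1.0 = perfectly uniform).  Rendering is fully
    deterministic given ``seed``.
    """

    shape: tuple[int, int] = (256, 256)
    resolution_um: float = 12.5
    background_level: float = BACKGROUND_LEVEL
    illumination_ratio: float = 1.0
    vessels: list[Vessel] = field(default_factory=list)
    drusen: list[ModifiedGaussian] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    roi_center: tuple[float, float] | None = None
    roi_diameter_um: float = 3000.0
    truth_threshold_frac: float = 0.18

    def center(self) -> tuple[float, float]:
        if self.roi_center is not None:
            return self.roi_center
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)


def default_phantom(
    seed: int = 0,
    n_drusen: int = 6,
    shape: tuple[int, int] = (256, 256),
    resolution_um: float = 12.5,
    amplitude_range: tuple[float, float] = (20.0, 40.0),
    sigma_range: tuple[float, float] = (4.0, 10.0),
    min_separation_sigmas: float = 4.0,
    noise_sd: float = 2.0,
    illumination_ratio: float = 1.0,
    n_vessels: int = 2,
) -> PhantomSpec:
    """Random phantom with well-separated drusen and crossing vessels.

    Drusen centres are drawn inside the ROI by rejection sampling so that any
    two centres are at least ``min_separation_sigmas`` times the larger of
    their widths apart and none sits on a vessel track.
    """
    rng = np.random.default_rng(seed)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    radius_px = 3000.0 / 2.0 / resolution_um

    # Arcade-like vessel layout: near-parallel chords on alternating sides of
    # the (avascular) fovea, random global orientation.  Macular vessels are
    # arcade branches that arch around the fovea and neither cross nor
    # overlap inside the ROI — which is also what the contrast reference
    # assumes (a single vessel per 250 µm window).
    base_ang = rng.uniform(0, np.pi)
    vessels: list[Vessel] = []
    for i in range(n_vessels):
        side = 1 if i % 2 == 0 else -1
        offset = side * rng.uniform(0.40, 0.65) * radius_px
        ang = base_ang + rng.normal(0.0, 0.08)
        dr, dc = np.sin(ang), np.cos(ang)
        nr, nc = -dc, dr
        p0 = (center[0] + nr * offset - dr * radius_px * 1.2,
              center[1] + nc * offset - dc * radius_px * 1.2)
        p1 = (center[0] + nr * offset + dr * radius_px * 1.2,
              center[1] + nc * offset + dc * radius_px * 1.2)
        vessels.append(Vessel(points=[p0, p1]))

    def vessel_dist(r: float, c: float) -> float:
        best = np.inf
        for v in vessels:
            (r0, c0), (r1, c1) = v.points[0], v.points[-1]
            dr_, dc_ = r1 - r0, c1 - c0
            t = np.clip(((r - r0) * dr_ + (c - c0) * dc_) / (dr_**2 + dc_**2), 0, 1)
            best = min(best, float(np.hypot(r - r0 - t * dr_, c - c0 - t * dc_)))
        return best

    drusen: list[ModifiedGaussian] = []
    attempts = 0
    while len(drusen) < n_drusen and attempts < 4000:
        attempts += 1
        rho = np.sqrt(rng.uniform(0, 1)) * radius_px * 0.8
        phi = rng.uniform(0, 2 * np.pi)
        r = center[0] + rho * np.sin(phi)
        c = center[1] + rho * np.cos(phi)
        sig = rng.uniform(*sigma_range)
        if vessel_dist(r, c) < 3.0 * sig:
            continue
        ok = True
        for g in drusen:
            sep = min_separation_sigmas * max(sig, g.sigma_x)
            if np.hypot(r - g.y0, c - g.x0) < sep:
                ok = False
                break
        if not ok:
            continue
        drusen.append(
            ModifiedGaussian(
                x0=c, y0=r, z0=0.0, A=rng.uniform(*amplitude_range),
                theta=rng.uniform(0, np.pi), sigma_x=sig,
                s_F=rng.uniform(0.8, 1.25), d=1.0,
            )
        )
    return PhantomSpec(
        shape=shape,
        resolution_um=resolution_um,
        illumination_ratio=illumination_ratio,
        vessels=vessels,
        drusen=drusen,
        noise_sd=noise_sd,
        seed=seed,
    )


def _illumination_field(shape: tuple[int, int], ratio: float) -> np.ndarray:
    """Smooth multiplicative field with the requested peak-to-trough ratio."""
    if ratio < 1.0:
        raise ValueError("illumination_ratio must be >= 1")
    if ratio == 1.0:
        return np.ones(shape)
    u = np.linspace(0.0, 1.0, shape[0])[:, None]
    v = np.linspace(0.0, 1.0, shape[1])[None, :]
    g = np.cos(np.pi * (u - 0.35)) * np.cos(0.8 * np.pi * (v - 0.25))
    g = (g - g.min()) / (g.max() - g.min()) * 2.0 - 1.0  # exact [-1, 1]
    a = np.log(ratio) / 2.0
    return np.exp(a * g)


def _vessel_drop(shape: tuple[int, int], vessels: list[Vessel],
                 resolution_um: float) -> np.ndarray:
    """Sum of Gaussian-profile intensity drops along the vessel tracks."""
    if not vessels:
        return np.zeros(shape)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    drop = np.zeros(shape)
    for v in vessels:
        sigma_px = (v.width_um / resolution_um) / 2.355  # FWHM -> sd
        d2 = np.full(shape, np.inf)
        pts = v.points
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            dr, dc = r1 - r0, c1 - c0
            L2 = dr * dr + dc * dc
            if L2 == 0:
                dd = (rr - r0) ** 2 + (cc - c0) ** 2
            else:
                t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / L2, 0.0, 1.0)
                dd = (rr - r0 - t * dr) ** 2 + (cc - c0 - t * dc) ** 2
            d2 = np.minimum(d2, dd)
        drop += v.depth * np.exp(-d2 / (2.0 * sigma_px**2))
    return drop


def analytic_drusen_area_px(g: ModifiedGaussian, level_margin: float) -> float:
    """Closed-form area (pixels) of {A*exp(-q^d) >= level_margin}.

    The super-level set is the ellipse q <= ln(A/L)^(1/d) with semi-axes
    sigma_x*sqrt(2t) and sigma_x*s_F*sqrt(2t); its area is
    2*pi*sigma_x^2*s_F*t.  Zero when the peak does not reach the level.
    """
    if level_margin <= 0:
        raise ValueError("level_margin must be > 0")
    if g.A < level_margin:
        return 0.0
    t = np.log(g.A / level_margin) ** (1.0 / g.d)
    return float(2.0 * np.pi * g.sigma_x**2 * g.s_F * t)


def render_phantom(
    spec: PhantomSpec,
) -> tuple[RetinalImage, GradingMask, pd.DataFrame]:
    """Render a phantom: image, analytic truth mask and drusen truth table.

    image = clip((background + sum drusen - sum vessel drops) * illumination
                 + noise, 0, 255); the truth mask is the analytic super-level
    set of background + drusen at background*(1 + truth_threshold_frac),
    restricted to the ROI.
    """
    shape = spec.shape
    rr, cc = np.meshgrid(np.arange(shape[0], dtype=float),
                         np.arange(shape[1], dtype=float), indexing="ij")
    drusen_sum = np.zeros(shape)
    for g in spec.drusen:
        drusen_sum += g.bump(rr, cc)
    clean = spec.background_level + drusen_sum - _vessel_drop(
        shape, spec.vessels, spec.resolution_um
    )
    field_ = _illumination_field(shape, spec.illumination_ratio)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, shape) if spec.noise_sd > 0 else 0.0
    img = RetinalImage(
        pixels=np.clip(clean * field_ + noise, 0.0, 255.0),
        resolution_um=spec.resolution_um,
        roi_center=spec.center(),
        roi_diameter_um=spec.roi_diameter_um,
    )
    level = spec.background_level * (1.0 + spec.truth_threshold_frac)
    truth = (spec.background_level + drusen_sum >= level) & roi_mask(img)
    rows = []
    margin = spec.background_level * spec.truth_threshold_frac
    for i, g in enumerate(spec.drusen):
        rows.append(
            {"id": i, "row": g.y0, "col": g.x0, "amplitude": g.A,
             "sigma_x": g.sigma_x, "s_F": g.s_F, "theta": g.theta, "d": g.d,
             "analytic_area_px": analytic_drusen_area_px(g, margin)}
        )
    params = pd.DataFrame(rows)
    return img, GradingMask(truth.astype(np.uint8), source="truth"), params


def simulate_experts(
    truth: GradingMask,
    n: int,
    boundary_jitter_px: float = 1.0,
    flip_rate: float = 0.0,
    seed: int = 0,
    roi: np.ndarray | None = None,
) -> list[GradingMask]:
    """Simulate expert gradings as perturbations of the truth mask.

    Each expert applies a random boundary perturbation — dilation or erosion
    by a disc whose radius is drawn from |N(0, jitter)| with random sign —
    followed by independent pixel flips at ``flip_rate`` (within the ROI when
    given).  Emulates the boundary subjectivity and slips of manual grading.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    base = truth.pixels
    sel = roi if roi is not None else np.ones(base.shape, dtype=bool)
    for e in range(n):
        m = base.copy()
        if boundary_jitter_px > 0:
            radius = int(round(abs(rng.normal(0.0, boundary_jitter_px))))
            if radius > 0:
                footprint = (np.hypot(*np.mgrid[-radius:radius + 1,
                                                -radius:radius + 1]) <= radius)
                if rng.random() < 0.5:
                    m = ndimage.binary_dilation(m, footprint)
                else:
                    m = ndimage.binary_erosion(m, footprint)
        if flip_rate > 0:
            flips = (rng.random(base.shape) < flip_rate) & sel
            m = np.where(flips, ~m, m)
        out.append(GradingMask(m.astype(np.uint8), source=f"expert{e + 1}"))
    return out
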