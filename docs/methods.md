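# Methods

This note records the model, the numerical choices, and what the synthetic
validation does and does not establish.

## Processing model

The measurement chain assumes an 8-bit fundus photograph whose green channel
carries the best drusen contrast, with known spatial resolution (µm/pixel)
and a user-supplied macula centre.  All analysis is restricted to the
region of interest (ROI), a 3000 µm disc around the macula centre (pixel
membership by Euclidean distance of pixel centres; coordinates are (row,
col), 0-based).  Intensities are floats throughout; quantization happens
only on export.

### Illumination correction

The illumination pattern is modelled as a smooth multiplicative field and
estimated by a cubic smoothing spline minimising

    p · Σᵢ (fᵢ − s(xᵢ))²  +  (1 − p) · ∫ |s″|² ,

fitted as a tensor product of 1-D smoothing splines (rows first, then
columns) with penalty weight λ = (1 − p)/p.  For tractability the fit uses a
decimated sample grid (default every 4th pixel); each retained sample
carries fidelity weight equal to the decimation factor so the decimated
objective approximates the full-grid one.  Without that weight the
effective stiffness is 16× too high and the fit under-tracks genuine
illumination gradients (measured as 23–30 % area drift under a ×1.5 field,
versus < 6 % with it).

**Smoothing factor vs resolution.**  The anchor is p = 1e-6 at
12.5 µm/pixel.  Re-expressing the objective in physical coordinates shows
the roughness term picks up a factor h⁻⁴ relative to the fidelity term for
pixel size h, so resolution-equivalent smoothing requires p(h) = 1e-6 ·
(h/12.5)⁴ — increasing with coarser sampling.  `calibrate_smoothing_factors`
verifies the law empirically: it renders the same physical illumination
gradient at several resolutions, flattens each, and reports the residual
background ripple (CV), which stays within 2× of the 12.5 µm reference.

**Masked refinement.**  Bright deposits bias the estimate upward, so the fit
iterates 5 times: fit, divide, cluster the ratio image, replace structure
pixels of the original with the fitted surface, refit.  Three choices here
are this package's own:

- the Otsu boundary for the bright (drusen) cluster is computed over ROI
  ratio pixels at or above the median.  With deep dark vessels in the
  histogram a plain two-class Otsu split lands between vessels and
  background, so the entire background joins the "bright" class; replacing
  it removes the anchor that holds the fit at the background level and the
  estimate sags progressively with each iteration;
- dark pixels are masked symmetrically (Otsu over the dark half): a
  roughness-penalized fit rings around a 50 %-contrast vessel exactly as it
  does around a bright deposit, and the ringing otherwise survives into the
  corrected image as vessel-flanking halos above the sectioning threshold;
- the replacement mask is dilated by a 3 px disc so structure flanks below
  the class threshold stop pulling the fit (without it, ~5 % of each
  druse's amplitude is absorbed into the illumination estimate).

After the last pass the ratio image is rescaled so its median ROI intensity
equals the nominal background level 85 (the scale after division is
otherwise arbitrary).  The correction is exactly invariant under a global
input gain.  Estimates that become non-positive inside the ROI raise a
diagnostic error rather than dividing through.

### Contrast normalization

RMS contrast of a window is defined as the standard deviation of its
intensities.  A square window of 250 µm (≈ twice a main vessel diameter)
slides with half-window stride over positions fully inside the ROI; the 51
windows with lowest mean intensity are kept and the overall contrast is the
median of their standard deviations.  (A figure caption in the source
material says 50 windows; the main text's 51 is adopted — both are config.)
The normalization is the affine map

    I′ = (I − b) · (15 / RMSc_overall) + 85,   clipped to [0, 255],

with b the median ROI intensity.  85 keeps 2/3 of the grey scale for bright
structures; 15 is the reference contrast.  The measurement window can be
manually relocated (`window_override` / `--contrast-window`) for images
where the automatic selection lands on an artefact.

### Gradient Path Labelling

Azimuths come from 3×3 Sobel responses, quantized to 8 compass sectors
(ties at the 22.5° boundaries round toward the smaller compass index); both
responses zero means "no direction".  The scan-order labelling propagates
each new label along ascent directions until the path leaves the mask,
reaches a directionless pixel, steps onto a pixel whose designated
neighbour is *lower* (a discrete summit — the azimuth is by definition the
ascending direction, so there is no ascending step left), or collides with
an existing label, which records an equivalence.  Equivalence groups are
replaced by their smallest member.  Directionless pixels adopt the label of
their first labelled 8-neighbour in scan order; isolated flat islands
become regions of their own and are handled by merging.  On plateau-free
images the resulting partition equals per-pixel steepest-ascent basin
assignment; the package ships the quadratic-time walker
(`steepest_ascent_basins`) as the validation reference.

**Merging.**  The region adjacency graph carries each region's maximum as
its node value and, per adjacent pair, the *saddle* of the shared border:
the maximum over facing 8-connected border pixel pairs of the lower of the
two intensities.  A region whose prominence (node minus its highest saddle)
is below Δa = 3 is absorbed into the neighbour across that saddle; rounds
are evaluated simultaneously against start-of-round state and repeated to a
fixed point, making the result independent of link enumeration order.  Two
details are deliberate: the link is the border's *highest* crossing (two
basins carved out of one smooth bump by azimuth quantization share a border
running from summit to skirt, and it is the top of that border that reveals
the split as an artefact), and each region merges only across its *best*
link (otherwise two prominent drusen are chained into one region through
the zero-prominence background region that borders both, and the second
modelling seed is lost).

### Modelling

Sections are 8-connected components of pixels more than 10 % above the
normalized background, bounding boxes padded by a quarter of the larger
extent (clamped to 3–10 px) of surrounding background.  Components smaller
than 4 px are discarded: even the smallest hard drusen (< 63 µm diameter)
span several pixels at the resolutions considered, so single-pixel
excursions are noise.  Segmentation maxima falling inside a component
become its seeds; a component without one is seeded at its brightest pixel.

Each section is fitted jointly — one Modified Gaussian per seed — by
constrained trust-region-reflective least squares (`scipy.optimize.
least_squares`; the classic Levenberg–Marquardt has no box support in
scipy, and the constraints are part of the contract).  Initialisation: seed
position, amplitude = seed intensity − background, σₓ from the equivalent
radius of the above-threshold footprint per seed, s_F = 1, θ = 0, d = 1.
Default boxes: A ∈ [0, 255 − background], σₓ ∈ [0.5, section extent],
s_F ∈ [0.2, 5], d ∈ [0.3, 3], θ ∈ [−π, π] (reported mod π); tolerances
1e-8, iteration cap 200 per parameter.  The baseline z₀ is pinned to the
shared background so each component has 7 free parameters; a `free_baseline`
flag restores per-component baselines at some stability cost.  A fit that
fails to converge keeps its initial parameters and flags the section rather
than aborting the image.

The image model renders as background + Σ(MG − z₀); by construction it is
never below background (amplitudes are non-negative).

### Quantification

The drusen mask is the rendered model's super-level set at
background · (1 + 0.18), restricted to the ROI — 100.3 at defaults.  The
threshold fraction is interpreted relative to the background constant,
parallel to the 10 % sectioning margin.  A component counts as a spot when
its own peak clears the threshold (A ≥ background · 0.18); spots whose
centres share a connected mask component are confluent.  Areas convert to
mm² via (µm/pixel / 1000)².  The global-threshold baseline marks normalized
pixels ≥ background · 1.30 directly and over-detects on noisy images by
construction.  `threshold_sweep` pools pixel confusion over image pairs for
thresholds 0–50 % (step 0.01) and reports the argmax-kappa threshold.

### Agreement statistics

Area CV is the sample (n−1) standard deviation over the mean, in percent.
ICC is the two-way random-effects, absolute-agreement, single-measure form
(ICC(A,1)/ICC2), computed by pingouin and cross-checked in the tests
against a direct ANOVA-decomposition evaluation; identical columns return
the degenerate limit 1.  Pixel sensitivity/specificity/kappa come from the
2×2 confusion counts over ROI pixels.  Consensus truth is a per-pixel
majority vote (ties marked).  Images whose expert-area CV exceeds 50 % are
flagged as outliers.  Per-grader scoring compares each grader with the
consensus of the others; per-image CV of a grading against its truth is the
two-value CV (|a − b|/√2 over the pair mean) and headline values average
the per-image metrics, with the ICC computed on the two area columns.

## Synthetic phantoms

`render_phantom` composes clip((background + Σ drusen − Σ vessel drops) ×
illumination + noise) with an analytic truth mask (the generating drusen
sum thresholded at the quantification level).  Defaults describe a
well-exposed macular photograph at 12.5 µm/pixel on a 256×256 grid:

- background 85 (the nominal normalized grey);
- two arcade-like vessels: near-parallel chords on opposite sides of the
  (avascular) fovea with random global orientation, Gaussian cross-section
  of 125 µm FWHM, centreline depth 42.2 — calibrated once so that the
  darkest-window RMS contrast of a flattened clean phantom equals the
  reference contrast 15 (independent random chords can overlap or cross
  inside the ROI, which both mis-states macular anatomy and violates the
  single-vessel-per-window premise of the contrast reference);
- six drusen with amplitudes 20–40, widths σₓ 4–10 px, mild ellipticity,
  centres kept 4σ apart and 3σ clear of vessels (the well-separated
  regime);
- additive Gaussian noise, sd 2 by default (clean variants set 0).

All randomness flows through one seeded generator; rendering is bit-exact
reproducible.  `simulate_experts` perturbs the truth mask per expert by a
random dilation/erosion (radius |N(0, jitter)|) plus independent pixel
flips, emulating boundary subjectivity and slips.

**What passing phantom tests shows — and does not.**  Phantom drusen are
exactly Modified Gaussians, so modelling-stage recovery on phantoms cannot
probe model misfit to real drusen shapes; vessels are straight and
constant-depth, there is no optic disc, no haemorrhages or exudates, no
film-grain correlation structure, and illumination fields are smooth
cosines.  End-to-end recovery on clean phantoms (count exact, area within
10 %, illumination drift < 10 %) validates the internal consistency of the
chain and its invariances, not clinical accuracy; the latter was
established in the original study against eight expert graders, whose
per-image areas and summary indicators ship with the package
(`ad3ri.datasets`) and anchor the agreement-statistics arithmetic.

## Problem sizes and numerical notes

Validation suites run at desk scale by design: 64×64 oracle phantoms (50
per run), 48×48 fitting sections, 256×256 end-to-end phantoms (a handful
per run).  The basin oracle is quadratic-time and intended for ≤ 64×64
instances.  Degenerate inputs are defined: constant images have zero
contrast (normalization refuses), zero-diameter ROIs contain only the
centre pixel, empty drusen lists render flat backgrounds and empty masks,
and a CV over a non-positive mean raises (an image where most graders mark
nothing has no meaningful relative spread; the outlier filter treats it as
an outlier).
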