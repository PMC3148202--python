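# ad3ri — automated drusen detection and quantification in retinal images

Drusen are extracellular deposits beneath the retina, visible in fundus
photographs as bright roundish spots, and a principal risk factor for
age-related macular degeneration (ARMD).  Following drusen load over years of
images requires a measurement that is reproducible — something manual grading
notoriously is not.  `ad3ri` implements an automated measurement chain for the
macular region of interest (the Wisconsin convention: a 3000 µm disc around
the macula centre), aimed at image-analysis researchers and grading-centre
tooling:

1. **Illumination correction** — a tensor-product cubic smoothing spline
   estimates the low-frequency illumination pattern by minimising
   `p·Σ(f−s)² + (1−p)·∫|s″|²`; the image is divided by the estimate.  Bright
   deposits (and dark vessels) are iteratively masked out of the fit via Otsu
   clustering of the ratio image, 5 passes by default.  The smoothing factor
   is anchored at `p = 1e-6` for 12.5 µm/pixel and scaled as `(h/12.5)⁴` for
   other resolutions.
2. **Contrast normalization** — a 250 µm window slides over the ROI; the 51
   darkest windows (typically single vessels over background) give the
   overall RMS contrast as the median of their per-window standard
   deviations.  Intensities are remapped affinely to reference contrast
   `RMSc = 15` over a constant background `A = 85`, keeping two thirds of the
   8-bit scale for bright structures.
3. **Gradient Path Labelling (GPL)** — every pixel's 3×3 Sobel azimuth is
   quantized to its 8-neighbour compass; labels propagate along ascent paths
   to intensity maxima, path collisions record label equivalences, and
   adjacent regions separated by a shallow saddle (peak − saddle < Δa = 3)
   are merged.  Each final region contributes its maximum as a drusen seed.
4. **Modified-Gaussian modelling** — the normalized image is cut into
   sections (connected components 10 % above background, padded with
   background); each section is fitted by one 8-parameter Modified Gaussian
   per seed,
   `MG(x,y) = z₀ + A·exp(−[x′²/2σₓ² + y′²/2(σₓ·s_F)²]^d)`,
   by constrained least squares — rotation θ, width σₓ, aspect `s_F`, and a
   profile exponent `d` spanning thin/bell/square shapes.
5. **Quantification** — the analytic model rendered and thresholded 18 %
   above background yields the drusen mask, spot count, total and mean area
   (mm²), and confluence; a classical 30 % global threshold on the pixels
   serves as the over-detecting baseline.  A sweep utility calibrates the
   threshold by maximising pixel-wise Cohen's kappa against ground truth.

An agreement module (CV of areas, ICC(A,1), pixel sensitivity/specificity/
kappa, majority-vote consensus truth, the >50 %-CV outlier policy, and
leave-one-out expert scoring) and a phantom generator with analytic ground
truth (background, arcade vessels, Modified-Gaussian drusen, multiplicative
illumination, noise) make every stage testable without clinical data.

## Worked example

```sh
python examples/01_phantom_pipeline.py
```

```
phantom drusen:        6
detected spots:        6
analytic truth area:   0.177 mm^2
quantified area:       0.170 mm^2
relative area error:   3.7%
confluent groups:      0
mean spot area:        0.0284 mm^2
```

The phantom embeds six Modified-Gaussian drusen with a closed-form truth mask
(the 18 % super-level set of the generating sum).  The pipeline recovers the
spot count exactly and the total affected area within a few percent; the
other examples demonstrate illumination invariance, the segmentation basins,
simulated grader panels, and the kappa threshold sweep.

The same chain is scriptable from the shell:

```sh
ad3ri synth --seed 3 --noise-sd 0 -o phantom.png --truth truth.png
ad3ri run phantom.png --resolution-um 12.5 --macula 127.5,127.5 -o out/
```

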