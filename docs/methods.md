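# Methods

## Gradient model

All measures operate on one fused gradient image per input. The image is
converted from sRGB (D65 white point, standard gamma expansion) to CIELAB;
embedded ICC profiles are ignored with a warning, since source color
profiles are generally unknown for mixed photograph/scan/download material.
Per channel, x/y derivatives use the centered-difference kernel
`[-1, 0, 1]/2`, with one-sided differences at the image borders rather than
padding — the simplest kernel consistent with classical HOG practice, and
the border policy touches well under 1 % of pixels at the default budget.
For each pixel the channel (L, a or b) with the largest magnitude supplies
both the strength and the orientation; orientation is the full signed
360° angle of `atan2(gy, gx)` (y increasing downward), set to 0 where the
strength is 0.

Because all three measures depend on resolution, images are first rescaled
isotropically (bicubic) so that `H·W` lands as close to a pixel budget as
integer rounding allows. The default budget is 10⁶ pixels; 10⁵ is the
conventional choice when comparing reproductions of mixed provenance, where
print halftoning aliases at the full budget. Resizing is always an explicit
pipeline stage — measurement functions never resize implicitly — so
resolution-sensitivity sweeps vary the budget alone. An image already at
(or rounding to) its own size is returned unchanged, which makes the
operation idempotent; genuine upsampling requires an explicit flag.

## PHOG decomposition and the three measures

The pyramid recursively splits each rectangle into 2×2 children (an odd
side gives the extra pixel to the left/top child), so level ℓ tiles the
image with exactly 4^ℓ sections. Each section's 16-bin orientation
histogram is magnitude-weighted with hard assignment; bin edges sit at
−11.25° + k·22.5°, so the cardinal orientations fall at bin centers instead
of being split across two bins. Detection-grade HOG's bilinear vote
interpolation is deliberately omitted: the measures describe gradient
statistics, not a matching descriptor. Zero-mass sections are flagged
degenerate and excluded from aggregation rather than normalized — small
sections with few gradients are statistically unstable, which is also why
self-similarity is conventionally read at level 3 and not deeper.

- **Complexity** is the arithmetic mean of the fused gradient strength over
  all pixels, in Lab units per pixel.
- **Self-similarity** at level ℓ is the median over non-degenerate sections
  of the Histogram Intersection Kernel with the ground-level histogram
  (mean aggregation is available as an option; the median follows PHOG
  self-similarity practice and is robust to a few degenerate-adjacent
  sections). Default level 3.
- **Anisotropy** at level ℓ is the population variance (divide by n) of the
  pooled normalized bin values of all non-degenerate sections — 16·4^ℓ
  values when none are degenerate. A per-section-variance-then-median
  variant is available. Default level 1.

## Frame estimators

The complexity of a frame cannot be measured in isolation: the inner border
between frame and painting contributes gradient mass of its own. Two
indirect estimators are implemented. The *difference estimator* subtracts
the complexity of the painting-only crop from that of the painting-with-
frame crop, both measured at the same pixel budget (mismatched budgets are
rejected; negative values are legal and kept). The *fill estimator*
replaces the painting's rectangle inside the PwF crop by a uniform field at
0, 50 or 100 % luminance — interpreted as Lab L = 0/50/100 with a = b = 0,
since the complexity measure itself is Lab-based — and measures the
complexity of the modified image. The fill happens in the full-resolution
crop before resizing by default (a flag reverses the order). Specific frame
complexity divides the gray-fill estimate by the frame's relative area
fraction. Frame geometry is always supplied (by the generator or a manifest
row), never detected: automatic frame segmentation is out of scope, and
non-rectangular inner borders are not supported.

## Synthetic scene generator

No museum-photograph dataset can be redistributed, so the pipeline's study
conditions are defined by a generator with measurable ground truth:

- **Paintings** are 1/f^α colored-noise canvases (default α = 2, the
  scale-invariant spectral slope typical of artworks), with the L channel
  scaled to a target contrast (standard deviation in L units, default 12)
  around mean L = 50, plus smoother independent a/b fields. A periodic-tile
  mode repeats one side/8 tile exactly, which forces level-3 section
  histograms to equal the ground histogram up to tile-seam pixels.
- **Frames** are rectangular bands (width a fraction of the painting width)
  whose molding profile is a sinusoid in the distance to the outer border,
  plus low-amplitude carving noise and a warm gilt tint. Gradient energy —
  and hence measured frame complexity — increases monotonically with the
  ornament amplitude, and the band's edges are purely cardinal.
- **Walls** are near-uniform with faint wallpaper noise under a smooth
  illumination ramp (default 10 L units across the scene in a random
  direction). The ramp is what real gallery walls contribute: wall sections
  carry few gradients, almost all pointing one way, so their histograms are
  spiky and intersect the ground histogram poorly — which is why
  self-similarity drops as the surround enters the crop.
- **Museum scenes** compose several shrunken framed paintings on a wide
  wall with floor/ceiling bands and vertical door edges, so cardinal
  orientations dominate the orientation histogram.

Three museum-style parameter presets (`old_masters`, `nineteenth`,
`modern`) couple frame width with ornament strength the way real
collections do: ornate frames are wide, plain frames are narrow. The preset
ranges were calibrated once, by measurement, so that generated PwF images
land in the observed ranges of real framed-painting photographs
(complexity ≈ 2–10, self-similarity ≈ 0.4–0.75, anisotropy ≈ 0.001–0.008,
specific frame complexity ≈ 3–18 with mean near 10). Within-preset painting
contrast dispersion is kept near the real data's (SD ≈ 1–1.5 around means
of 4–7): both the coupling and the dispersion matter for the agreement
between the two frame-complexity estimators, which share frame-gradient
mass as their common driver but differ by a term proportional to painting
complexity times frame-area fraction. Randomizing width and ornament
independently would manufacture wide-but-plain frames that museums do not
hang, and for those the estimators genuinely diverge.

What passing tests on this generator do *not* show: real paintings have
compositional and object structure that homogeneous noise lacks, so the
generator's painting-only images are more self-similar (≈ 0.9 at level 3)
than real paintings; absolute P-category values should not be compared to
published museum numbers, only the PwF ranges and the category *orderings*
should. Depth relief of real frames (lighting-dependent shading) is not
modelled; frames are flat textures.

## Batch analysis and statistics

`analyze_manifest` measures every record and every resolvable P/PwF pair,
logging and skipping unreadable images or missing pair members rather than
failing. Category/group comparisons use the Kruskal–Wallis H test
(tie-corrected, via scipy) with Dunn's pairwise post-test: z statistics on
pooled mean ranks with the standard tie term, two-sided normal p-values,
and Bonferroni adjustment across all pairs by default (Holm optional; the
Bonferroni variant is the classical Dunn procedure). Effect sizes are
Cohen's d with (n−1)-weighted pooled SD. Spearman correlations use a
pairings permutation test for n ≤ 12 (exhaustive up to n = 8) and the
asymptotic approximation otherwise. All tests are two-tailed. Significance
is reported in the tiers < 0.05, < 0.01, < 0.001, ns.

## Numerical and scale choices

- Synthetic-batch analyses (estimator agreement, category orderings) run at
  the generator's native ≈ 0.1-megapixel scene scale rather than the
  10⁶-pixel budget: category orderings are robust across resolutions, and
  this keeps batch runs cheap. The million-pixel budget is exercised by the
  periodic-tile self-similarity check, which generates at exactly
  1000×1000 so no resampling perturbs the tiling.
- Ties in the per-pixel channel-max fusion resolve to the first channel in
  (L, a, b) order; for achromatic pixels this is the L channel.
- Histograms are validated to sum to 1 within 1e-9; degenerate sections are
  excluded, and operations where *all* sections are degenerate raise a
  diagnostic error instead of returning a number.
- The Dunn null-calibration and all generator draws derive from explicit
  seeds; regeneration from (spec, seed) is byte-identical.

## Known limitations

- No ICC-aware color management, RAW decoding or lens-distortion handling;
  inputs are assumed plain sRGB.
- Frame geometry must be axis-aligned rectangles supplied by the caller.
- The generator emulates statistical structure, not appearance; it is not a
  painting synthesizer, and its museum scenes contain no visitors.
- Dunn–Bonferroni is conservative; under the null its per-pair rejection
  rate sits well below the nominal 5 %.
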