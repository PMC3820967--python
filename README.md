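# framesip

Statistical image properties of framed paintings and museum scenes.

When an observer zooms out from a painting to the painting with its frame
(PwF), to the framed painting with its wall surround (PwF/S), and finally to
a wide museum-scene view (MSc), the low-level statistics of the retinal
image change systematically. `framesip` measures three gradient-based
higher-order image properties across this zoom-out sequence, plus a set of
frame-specific estimators, and provides the non-parametric statistics used
to compare scene categories and collections. Because museum photograph
datasets are copyrighted and not distributable, the package ships a
synthetic museum-scene generator that emulates the statistical structure of
each category, so the whole pipeline is testable end to end.

It is aimed at researchers in experimental aesthetics and computational
image-statistics who want a reproducible implementation of these measures.

## The measures

All three properties are computed from a single fused gradient image. The
input is converted to CIELAB; oriented luminance gradients are computed per
channel with the centered-difference kernel `[-1, 0, 1]` (one-sided at
borders); per pixel, the channel with the largest magnitude
`sqrt(gx² + gy²)` supplies both the gradient strength and its orientation
`atan2(gy, gx)`. Images are first reduced to a fixed pixel budget (default
10⁶ pixels) by isotropic bicubic scaling.

On top of the gradient image, a PHOG (Pyramid of Histograms of Oriented
Gradients) decomposition recursively splits the image into 4^ℓ rectangular
sections per level ℓ; each section gets a 16-bin orientation histogram over
360° in which every pixel votes its gradient magnitude, normalized to unit
sum. Then:

- **complexity** — mean gradient strength over all pixels (ground level);
- **self-similarity** — median, over the sections at a level (default 3),
  of the Histogram Intersection Kernel `HIK(h, g) = Σᵢ min(hᵢ, gᵢ)` between
  the section histogram and the ground-level histogram;
- **anisotropy** — population variance of the normalized bin values at a
  level (default 1); 0 when all orientations carry equal gradient mass.

Frame-specific measures for P/PwF pairs:

- **frame-area percent** — frame pixel area as a percentage of the PwF crop;
- **difference estimator** — `complexity(PwF) − complexity(P)`;
- **fill estimator** — complexity of the PwF image after the painting's
  rectangle is replaced by a uniform field at 0/50/100 % luminance
  (Lab L = 0/50/100);
- **specific frame complexity** — gray-fill estimate divided by the frame's
  relative area: complexity per unit of frame area.

## Worked example

```python
import framesip as fs
from framesip.synthetic import SceneSpec, compose_family

fam = compose_family(SceneSpec(seed=5))          # P / PwF / PwF_S / MSc
for cat in ("P", "PwF", "PwF_S", "MSc"):
    sip = fs.measure_image(fam[cat])             # native resolution
    print(f"{cat:6s} complexity={sip.complexity:5.2f} "
          f"self_similarity={sip.self_similarity:.3f} "
          f"anisotropy={sip.anisotropy:.5f}")

geom = fam["geometry"]
fill = fs.frame_complexity_fill(fam["PwF"], geom, 50, budget=None)
area = fs.frame_area_percent(geom)
print(f"frame area {area:.1f}%  gray-fill complexity {fill:.2f}  "
      f"specific {fs.specific_frame_complexity(fill, area):.1f}")
```

prints

```
P      complexity= 6.18 self_similarity=0.948 anisotropy=0.00000
PwF    complexity= 6.83 self_similarity=0.732 anisotropy=0.00139
PwF_S  complexity= 2.77 self_similarity=0.736 anisotropy=0.00143
MSc    complexity= 1.29 self_similarity=0.560 anisotropy=0.00652
frame area 40.9%  gray-fill complexity 3.21  specific 7.8
```

The frame band raises complexity above the painting alone and adds cardinal
orientation structure (higher anisotropy); the painting alone is the most
self-similar category, and zooming out into the wall surround and the
museum scene lowers complexity again. (Category orderings are asserted on
batch means — single families fluctuate.) Numbers from your own run will
match these exactly: generation is deterministic per seed.

A command-line interface wraps the same functions:

```bash
framesip synth --groups 3 --families 30 --seed 17 --out scenes/
framesip frames --manifest scenes/manifest.csv --budget 0 --fills 0,50,100
framesip compare --results results_images.csv --out report/
framesip measure scenes/*_P.png --budget 0
```

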