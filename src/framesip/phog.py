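"""Pyramid of Histograms of Oriented Gradients (PHOG) and the three
statistical image properties derived from it.

The image is partitioned recursively into 4^l rectangular sections per
pyramid level l (level 0 is the whole image).  Each section gets a 16-bin
orientation histogram over 360 degrees, where every pixel votes its gradient
magnitude into the bin holding its orientation, and the histogram is then
normalized to unit sum.  From the pyramid:

* complexity   -- mean gradient strength over all pixels of the fused
                  gradient image (ground level);
* self-similarity -- aggregate Histogram Intersection Kernel similarity
                  between the section histograms at a level (default 3) and
                  the ground-level histogram;
* anisotropy   -- variance of the normalized bin strengths at a level
                  (default 1); 0 when all orientations carry equal mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield

import numpy as np

from .gradients import GradientField, RasterImage, gradient_field, resize_to_budget

__all__ = [
    "measure_image",
    "N_BINS",
    "BIN_WIDTH_DEG",
    "BIN_OFFSET_DEG",
    "OrientationHistogram",
    "PyramidHOG",
    "SIPResult",
    "orientation_bin_index",
    "build_pyramid",
    "histogram_intersection",
    "self_similarity",
    "complexity",
    "anisotropy",
    "DegenerateHistogramError",
]

N_BINS = 16
BIN_WIDTH_DEG = 360.0 / N_BINS
# Bin edges sit at -11.25 + k*22.5 degrees so that the cardinal orientations
# (0, 90, 180, 270) fall at bin centers instead of being split across bins.
BIN_OFFSET_DEG = -BIN_WIDTH_DEG / 2.0

DEFAULT_LMAX = 3
MAX_LEVEL = 4
DEFAULT_SS_LEVEL = 3
DEFAULT_ANISO_LEVEL = 1


class DegenerateHistogramError(ValueError):
    """Raised when an operation receives a zero-gradient-mass histogram."""


@dataclass(frozen=True)
class OrientationHistogram:
    """Normalized 16-bin histogram of oriented gradient mass in a section.

    ``raw_mass`` is the total unnormalized gradient magnitude; a section with
    zero mass is flagged ``degenerate`` (bins all zero) instead of being
    normalized.
    """

    bins: np.ndarray
    raw_mass: float

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=np.float64)
        if b.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got shape {b.shape}")
        if not self.degenerate and abs(b.sum() - 1.0) > 1e-9:
            raise ValueError(f"normalized bins must sum to 1, got {b.sum()!r}")
        object.__setattr__(self, "bins", b)

    @property
    def degenerate(self) -> bool:
        return self.raw_mass == 0.0


@dataclass(frozen=True)
class PyramidHOG:
    """Section rectangles and histograms for pyramid levels 0..lmax.

    ``rects[l]`` is a list of 4^l half-open pixel rectangles
    ``(r0, c0, r1, c1)`` that tile the image exactly; ``hists[l]`` the
    matching histograms.
    """

    rects: tuple[tuple[tuple[int, int, int, int], ...], ...]
    hists: tuple[tuple[OrientationHistogram, ...], ...] = _dcfield(repr=False)

    @property
    def lmax(self) -> int:
        return len(self.rects) - 1

    @property
    def ground(self) -> OrientationHistogram:
        return self.hists[0][0]

    def degenerate_count(self, level: int) -> int:
        return sum(h.degenerate for h in self.hists[level])


@dataclass(frozen=True)
class SIPResult:
    """The three statistical image properties of one image."""

    complexity: float
    self_similarity: float
    anisotropy: float
    ss_level: int = DEFAULT_SS_LEVEL
    aniso_level: int = DEFAULT_ANISO_LEVEL
    pixel_budget: int | None = None
    degenerate_sections: int = 0


def orientation_bin_index(orientation_deg: np.ndarray) -> np.ndarray:
    """Hard-assign orientations in [0, 360) to the 16 bins.

    Bin k covers [-11.25 + k*22.5, -11.25 + (k+1)*22.5) degrees mod 360.
    """
    idx = np.floor((np.asarray(orientation_deg) - BIN_OFFSET_DEG) / BIN_WIDTH_DEG)
    return idx.astype(np.int64) % N_BINS


def _split(lo: int, hi: int) -> int:
    """Midpoint of a half-open span; an odd span gives the extra pixel to the
    left/top part."""
    return lo + (hi - lo + 1) // 2


def build_pyramid(field: GradientField, lmax: int = DEFAULT_LMAX) -> PyramidHOG:
    """Compute the section pyramid of magnitude-weighted orientation
    histograms for levels 0..lmax.

    Sections are produced by recursive 2x2 splitting with integer halving
    (odd side: the left/top child gets the extra pixel), so level l tiles the
    image with exactly 4^l rectangles.
    """
    if not 0 <= lmax <= MAX_LEVEL:
        raise ValueError(f"lmax must be in [0, {MAX_LEVEL}], got {lmax}")
    h, w = field.shape
    need = 2**lmax
    for side, name in ((h, "height"), (w, "width")):
        if side < need:
            raise ValueError(
                f"image {name} {side} too small for pyramid level {lmax} "
                f"(needs >= {need})"
            )

    bin_idx = orientation_bin_index(field.orientation)
    strength = field.strength

    def hist_of(rect):
        r0, c0, r1, c1 = rect
        counts = np.bincount(
            bin_idx[r0:r1, c0:c1].ravel(),
            weights=strength[r0:r1, c0:c1].ravel(),
            minlength=N_BINS,
        )
        mass = float(counts.sum())
        if mass == 0.0:
            return OrientationHistogram(np.zeros(N_BINS), 0.0)
        return OrientationHistogram(counts / mass, mass)

    rects_per_level: list[tuple] = [((0, 0, h, w),)]
    for _ in range(lmax):
        children = []
        for r0, c0, r1, c1 in rects_per_level[-1]:
            rm, cm = _split(r0, r1), _split(c0, c1)
            children += [
                (r0, c0, rm, cm),
                (r0, cm, rm, c1),
                (rm, c0, r1, cm),
                (rm, cm, r1, c1),
            ]
        rects_per_level.append(tuple(children))

    hists = tuple(tuple(hist_of(r) for r in rl) for rl in rects_per_level)
    return PyramidHOG(tuple(rects_per_level), hists)


def histogram_intersection(
    h: OrientationHistogram, g: OrientationHistogram
) -> float:
    """Histogram Intersection Kernel similarity: sum_i min(h_i, g_i).

    1 for identical normalized histograms, 0 for disjoint support.
    """
    if h.degenerate or g.degenerate:
        raise DegenerateHistogramError(
            "histogram intersection is undefined for zero-mass sections; "
            "filter degenerate sections first"
        )
    return float(np.minimum(h.bins, g.bins).sum())


def self_similarity(
    pyr: PyramidHOG, level: int = DEFAULT_SS_LEVEL, *, stat: str = "median"
) -> float:
    """Aggregate HIK similarity of level-`level` sections to the ground level.

    Degenerate (zero-mass) sections are excluded; the count is available via
    ``pyr.degenerate_count(level)``.  ``stat`` selects the aggregation across
    sections ('median', the default, or 'mean').
    """
    if not 1 <= level <= pyr.lmax:
        raise ValueError(f"level must be in [1, {pyr.lmax}], got {level}")
    ground = pyr.ground
    if ground.degenerate:
        raise DegenerateHistogramError("ground-level histogram has zero mass")
    vals = [
        histogram_intersection(h, ground)
        for h in pyr.hists[level]
        if not h.degenerate
    ]
    if not vals:
        raise DegenerateHistogramError(
            f"all {4**level} sections at level {level} are degenerate"
        )
    if stat == "median":
        return float(np.median(vals))
    if stat == "mean":
        return float(np.mean(vals))
    raise ValueError(f"stat must be 'median' or 'mean', got {stat!r}")


def complexity(field: GradientField) -> float:
    """Mean gradient strength over all pixels of the fused gradient image."""
    return float(field.strength.mean())


def anisotropy(
    pyr: PyramidHOG, level: int = DEFAULT_ANISO_LEVEL, *, pooling: str = "pooled"
) -> float:
    """Variance of the normalized orientation-bin values at a pyramid level.

    With the default pooled convention, the population variance (divide by n)
    is taken over the 16 * 4^level bin values of all non-degenerate sections.
    ``pooling='per_section'`` instead takes the median of per-section
    population variances.
    """
    if not 0 <= level <= pyr.lmax:
        raise ValueError(f"level must be in [0, {pyr.lmax}], got {level}")
    bins = [h.bins for h in pyr.hists[level] if not h.degenerate]
    if not bins:
        raise DegenerateHistogramError(
            f"all sections at level {level} are degenerate"
        )
    if pooling == "pooled":
        return float(np.var(np.concatenate(bins)))
    if pooling == "per_section":
        return float(np.median([np.var(b) for b in bins]))
    raise ValueError(f"pooling must be 'pooled' or 'per_section', got {pooling!r}")


def measure_image(
    img: RasterImage,
    *,
    budget: int | None = None,
    ss_level: int = DEFAULT_SS_LEVEL,
    aniso_level: int = DEFAULT_ANISO_LEVEL,
    lmax: int = DEFAULT_LMAX,
    ss_stat: str = "median",
    aniso_pooling: str = "pooled",
    allow_upsample: bool = False,
) -> SIPResult:
    """Full pipeline for one image: resize to the pixel budget (when given),
    convert to Lab, fuse channel gradients, build the PHOG pyramid, and
    return complexity, self-similarity and anisotropy.

    ``budget=None`` measures at native resolution; resizing is always this
    explicit stage, never implicit in the measures, so resolution-sensitivity
    sweeps can vary the budget alone.
    """
    if budget is not None:
        img = resize_to_budget(img, budget, allow_upsample=allow_upsample)
    field = gradient_field(img)
    pyr = build_pyramid(field, max(lmax, ss_level, aniso_level))
    return SIPResult(
        complexity=complexity(field),
        self_similarity=self_similarity(pyr, ss_level, stat=ss_stat),
        anisotropy=anisotropy(pyr, aniso_level, pooling=aniso_pooling),
        ss_level=ss_level,
        aniso_level=aniso_level,
        pixel_budget=budget,
        degenerate_sections=pyr.degenerate_count(ss_level),
    )
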