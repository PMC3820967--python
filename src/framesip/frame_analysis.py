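"""Frame-specific measures for painting / painting-with-frame image pairs.

A framed painting's frame cannot be measured in isolation, because the inner
border between frame and painting contributes gradient mass of its own.  Two
indirect estimators are therefore used:

* difference estimator -- complexity(PwF) - complexity(P) for a paired crop
  of the same painting with and without its frame;
* fill estimator -- complexity of the PwF image after the painting's inner
  rectangle is replaced by a uniform rectangle at 0/50/100 % luminance
  (Lab L = 0/50/100, a = b = 0).

Dividing the gray-fill estimate by the frame's relative area in the PwF crop
gives the *specific frame complexity* (complexity per unit of frame area).

Scene categories follow the zoom-out sequence painting only (P), painting
with frame (PwF), framed painting with surround about twice the painting's
width (PwF/S), and wide museum scene (MSc).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gradients import (
    DEFAULT_PIXEL_BUDGET,
    RasterImage,
    lab_to_srgb,
    load_image,
    to_lab,
)
from .phog import SIPResult, measure_image

__all__ = [
    "CATEGORIES",
    "FrameGeometry",
    "FrameMeasures",
    "SceneRecord",
    "frame_area_percent",
    "frame_complexity_difference",
    "frame_complexity_fill",
    "compute_frame_measures",
    "specific_frame_complexity",
    "analyze_manifest",
    "read_manifest",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("P", "PwF", "PwF_S", "MSc")

#: Luminance levels (percent) used by the fill estimator.
FILL_LEVELS = (0, 50, 100)


@dataclass(frozen=True)
class FrameGeometry:
    """Pixel geometry of a framed painting within its PwF crop.

    ``outer`` is the full PwF rectangle, ``inner`` the painting's rectangle,
    both half-open ``(x0, y0, x1, y1)`` in 0-based pixel coordinates with the
    inner strictly inside the outer.  ``physical_painting_area`` optionally
    records the catalog size of the painting in square meters.
    """

    outer: tuple[int, int, int, int]
    inner: tuple[int, int, int, int]
    physical_painting_area: float | None = None

    def __post_init__(self) -> None:
        ox0, oy0, ox1, oy1 = self.outer
        ix0, iy0, ix1, iy1 = self.inner
        if not (ox0 < ox1 and oy0 < oy1):
            raise ValueError(f"degenerate outer rectangle {self.outer}")
        if not (ix0 < ix1 and iy0 < iy1):
            raise ValueError(f"degenerate inner rectangle {self.inner}")
        if not (ox0 <= ix0 and oy0 <= iy0 and ix1 <= ox1 and iy1 <= oy1):
            raise ValueError(
                f"inner rectangle {self.inner} not inside outer {self.outer}"
            )
        if (ix0, iy0, ix1, iy1) == (ox0, oy0, ox1, oy1):
            raise ValueError("inner rectangle equals outer: no frame band")

    @property
    def outer_area(self) -> int:
        x0, y0, x1, y1 = self.outer
        return (x1 - x0) * (y1 - y0)

    @property
    def inner_area(self) -> int:
        x0, y0, x1, y1 = self.inner
        return (x1 - x0) * (y1 - y0)

    def scaled(self, sx: float, sy: float) -> "FrameGeometry":
        """Geometry after isotropic-ish rescaling of the PwF crop."""

        def sc(rect):
            x0, y0, x1, y1 = rect
            return (
                int(round(x0 * sx)),
                int(round(y0 * sy)),
                max(int(round(x1 * sx)), int(round(x0 * sx)) + 1),
                max(int(round(y1 * sy)), int(round(y0 * sy)) + 1),
            )

        return FrameGeometry(sc(self.outer), sc(self.inner), self.physical_painting_area)


@dataclass(frozen=True)
class FrameMeasures:
    """Frame-complexity estimates for one P/PwF pair."""

    id: str
    frame_area_percent: float
    delta_complexity: float | None
    fill_complexity: dict[int, float]
    specific_complexity: float


@dataclass(frozen=True)
class SceneRecord:
    """One manifest row: an image of one scene category.

    ``image`` may carry an in-memory :class:`RasterImage`; otherwise the
    record's ``path`` is read on demand.  P/PwF records of the same painting
    share an ``id`` stem; PwF records carry the frame geometry.
    """

    id: str
    group: str
    category: str
    path: str | None = None
    source: str = "synthetic"
    geometry: FrameGeometry | None = None
    image: RasterImage | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )

    def load(self) -> RasterImage:
        if self.image is not None:
            return self.image
        if self.path is None:
            raise ValueError(f"record {self.id}/{self.category} has no image or path")
        return load_image(self.path)


def frame_area_percent(geom: FrameGeometry) -> float:
    """Frame area as a percentage of the total PwF image area."""
    return (1.0 - geom.inner_area / geom.outer_area) * 100.0


def frame_complexity_difference(p: SIPResult, pwf: SIPResult) -> float:
    """Difference estimator: complexity(PwF) - complexity(P).

    Negative values are legal (a plain frame around a busy painting) and are
    reported with their sign.  Both results must come from the same pixel
    budget, otherwise the difference mixes resolution effects.
    """
    if p.pixel_budget != pwf.pixel_budget:
        raise ValueError(
            f"pixel budgets differ: P at {p.pixel_budget}, PwF at {pwf.pixel_budget}"
        )
    return pwf.complexity - p.complexity


def fill_inner_rectangle(
    pwf_img: RasterImage, geom: FrameGeometry, luminance: int
) -> RasterImage:
    """Replace the painting's inner rectangle by a uniform field of the given
    luminance (percent -> Lab L, with a = b = 0), rendered in the image's own
    color space."""
    if luminance not in FILL_LEVELS:
        raise ValueError(f"luminance must be one of {FILL_LEVELS}, got {luminance}")
    ox0, oy0, ox1, oy1 = geom.outer
    if ox1 > pwf_img.width or oy1 > pwf_img.height:
        raise ValueError(
            f"geometry outer {geom.outer} exceeds image "
            f"{pwf_img.width}x{pwf_img.height}"
        )
    if luminance == 0:
        fill_l = 0.0
    elif luminance == 100:
        fill_l = 100.0
    else:
        fill_l = 50.0
    if pwf_img.color_space == "Lab":
        fill = np.array([fill_l, 0.0, 0.0])
    else:
        fill = lab_to_srgb(np.array([[[fill_l, 0.0, 0.0]]]))[0, 0]
    px = pwf_img.pixels.copy()
    x0, y0, x1, y1 = geom.inner
    px[y0:y1, x0:x1, :] = fill
    return RasterImage(px, pwf_img.color_space)


def frame_complexity_fill(
    pwf_img: RasterImage,
    geom: FrameGeometry,
    luminance: int = 50,
    *,
    budget: int | None = DEFAULT_PIXEL_BUDGET,
    fill_after_resize: bool = False,
    allow_upsample: bool = False,
) -> float:
    """Fill estimator of frame complexity at one luminance level.

    By default the fill happens in the full-resolution crop and the modified
    image is then resized to the working budget; ``fill_after_resize``
    reverses the order (the geometry is rescaled to match).
    """
    from .gradients import resize_to_budget
    from .phog import complexity as _complexity
    from .gradients import gradient_field

    if fill_after_resize and budget is not None:
        resized = resize_to_budget(pwf_img, budget, allow_upsample=allow_upsample)
        sx = resized.width / pwf_img.width
        sy = resized.height / pwf_img.height
        modified = fill_inner_rectangle(resized, geom.scaled(sx, sy), luminance)
        return _complexity(gradient_field(to_lab(modified)))
    modified = fill_inner_rectangle(pwf_img, geom, luminance)
    if budget is not None:
        modified = resize_to_budget(modified, budget, allow_upsample=allow_upsample)
    return _complexity(gradient_field(to_lab(modified)))


def specific_frame_complexity(fill_value: float, frame_area: float) -> float:
    """Frame complexity per unit of relative frame area:
    ``fill_value / (frame_area / 100)``.

    ``frame_area`` is the frame-area percentage of the PwF crop; a zero area
    leaves the quantity undefined (NaN).
    """
    if frame_area < 0.0 or frame_area > 100.0:
        raise ValueError(f"frame_area must be a percentage in [0, 100], got {frame_area}")
    if frame_area == 0.0:
        logger.warning("specific frame complexity undefined for zero frame area")
        return math.nan
    return fill_value / (frame_area / 100.0)


def compute_frame_measures(
    p_img: RasterImage | None,
    pwf_img: RasterImage,
    geom: FrameGeometry,
    *,
    id: str = "",
    budget: int | None = DEFAULT_PIXEL_BUDGET,
    fills: tuple[int, ...] = FILL_LEVELS,
    allow_upsample: bool = False,
) -> FrameMeasures:
    """All frame measures for one P/PwF pair (difference estimator skipped
    when the P image is unavailable)."""
    area = frame_area_percent(geom)
    delta = None
    if p_img is not None:
        delta = frame_complexity_difference(
            measure_image(p_img, budget=budget, allow_upsample=allow_upsample),
            measure_image(pwf_img, budget=budget, allow_upsample=allow_upsample),
        )
    fill_vals = {
        lum: frame_complexity_fill(
            pwf_img, geom, lum, budget=budget, allow_upsample=allow_upsample
        )
        for lum in fills
    }
    gray = fill_vals.get(50, next(iter(fill_vals.values())))
    return FrameMeasures(
        id=id,
        frame_area_percent=area,
        delta_complexity=delta,
        fill_complexity=fill_vals,
        specific_complexity=specific_frame_complexity(gray, area),
    )


# ---------------------------------------------------------------------------
# Batch analysis over a manifest


def read_manifest(path) -> list[SceneRecord]:
    """Read a manifest CSV into scene records.

    Expected columns: id, group, category, source, path, and for PwF rows the
    half-open 0-based inner-rectangle pixel coordinates inner_x0, inner_y0,
    inner_x1, inner_y1 (the outer rectangle is the full image), plus optional
    painting_w_m, painting_h_m catalog dimensions.
    """
    df = pd.read_csv(path)
    base = Path(path).parent
    records = []
    for row in df.itertuples(index=False):
        geom = None
        if row.category == "PwF" and not pd.isna(getattr(row, "inner_x0", np.nan)):
            img_path = base / str(row.path)
            from PIL import Image as _PILImage

            with _PILImage.open(img_path) as im:
                w, h = im.size
            area = None
            if not pd.isna(getattr(row, "painting_w_m", np.nan)):
                area = float(row.painting_w_m) * float(row.painting_h_m)
            geom = FrameGeometry(
                outer=(0, 0, w, h),
                inner=(
                    int(row.inner_x0),
                    int(row.inner_y0),
                    int(row.inner_x1),
                    int(row.inner_y1),
                ),
                physical_painting_area=area,
            )
        records.append(
            SceneRecord(
                id=str(row.id),
                group=str(row.group),
                category=str(row.category),
                path=str(base / str(row.path)),
                source=str(getattr(row, "source", "photo")),
                geometry=geom,
            )
        )
    return records


def analyze_manifest(
    records: list[SceneRecord],
    *,
    budget: int | None = DEFAULT_PIXEL_BUDGET,
    ss_level: int = 3,
    aniso_level: int = 1,
    fills: tuple[int, ...] = (50,),
    allow_upsample: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every record and every resolvable P/PwF pair.

    Returns ``(per_image, pairs)``: one row per readable record with the
    three statistical image properties, and one row per P/PwF id pair with
    the frame measures.  Unreadable images or missing pair members are logged
    and skipped, never fatal.
    """
    rows = []
    by_key: dict[tuple[str, str], tuple[SceneRecord, SIPResult]] = {}
    for rec in records:
        try:
            img = rec.load()
            sip = measure_image(
                img,
                budget=budget,
                ss_level=ss_level,
                aniso_level=aniso_level,
                allow_upsample=allow_upsample,
            )
        except Exception as exc:  # noqa: BLE001 - partial failure contract
            logger.error("record %s/%s failed: %s", rec.id, rec.category, exc)
            continue
        by_key[(rec.id, rec.category)] = (rec, sip)
        rows.append(
            {
                "id": rec.id,
                "group": rec.group,
                "category": rec.category,
                "source": rec.source,
                "complexity": sip.complexity,
                "self_similarity": sip.self_similarity,
                "anisotropy": sip.anisotropy,
                "ss_level": ss_level,
                "aniso_level": aniso_level,
                "pixel_budget": budget,
                "degenerate_sections": sip.degenerate_sections,
            }
        )
    per_image = pd.DataFrame(
        rows,
        columns=[
            "id", "group", "category", "source", "complexity",
            "self_similarity", "anisotropy", "ss_level", "aniso_level",
            "pixel_budget", "degenerate_sections",
        ],
    ).sort_values(["group", "id", "category"], kind="stable").reset_index(drop=True)

    pair_rows = []
    pwf_ids = sorted({k[0] for k in by_key if k[1] == "PwF"})
    for pid in pwf_ids:
        pwf_rec, pwf_sip = by_key[(pid, "PwF")]
        if pwf_rec.geometry is None:
            logger.warning("PwF record %s has no frame geometry; skipped", pid)
            continue
        area_pct = frame_area_percent(pwf_rec.geometry)
        delta = None
        if (pid, "P") in by_key:
            delta = frame_complexity_difference(by_key[(pid, "P")][1], pwf_sip)
        else:
            logger.warning("no P image for id %s; difference estimator skipped", pid)
        pwf_img = pwf_rec.load()
        fill_vals = {
            lum: frame_complexity_fill(
                pwf_img, pwf_rec.geometry, lum,
                budget=budget, allow_upsample=allow_upsample,
            )
            for lum in fills
        }
        gray = fill_vals.get(50, next(iter(fill_vals.values())))
        pair_rows.append(
            {
                "id": pid,
                "group": pwf_rec.group,
                "frame_area_percent": area_pct,
                "delta_complexity": delta,
                **{f"fill_complexity_{lum}": v for lum, v in fill_vals.items()},
                "specific_frame_complexity": specific_frame_complexity(gray, area_pct),
                "physical_painting_area_m2": (
                    pwf_rec.geometry.physical_painting_area
                ),
            }
        )
    pairs = pd.DataFrame(pair_rows)
    if not pairs.empty:
        pairs = pairs.sort_values(["group", "id"], kind="stable").reset_index(drop=True)
    return per_image, pairs
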