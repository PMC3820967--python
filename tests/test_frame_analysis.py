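"""Frame geometry, the two frame-complexity estimators, and manifest-driven
batch analysis."""

import logging

import numpy as np
import pandas as pd
import pytest
from skimage.transform import resize as skresize

from framesip import (
    FrameGeometry,
    RasterImage,
    analyze_manifest,
    complexity,
    frame_area_percent,
    frame_complexity_difference,
    frame_complexity_fill,
    gradient_field,
    measure_image,
    read_manifest,
    specific_frame_complexity,
)
from framesip.frame_analysis import SceneRecord, fill_inner_rectangle
from framesip.synthetic import (
    FrameParams,
    SceneSpec,
    compose_family,
    write_batch,
)


class TestGeometry:
    def test_area_percent_square_example(self):
        geom = FrameGeometry(outer=(0, 0, 100, 100), inner=(10, 10, 90, 90))
        assert frame_area_percent(geom) == pytest.approx(36.0)

    def test_inner_outside_outer_rejected(self):
        with pytest.raises(ValueError, match="not inside"):
            FrameGeometry(outer=(0, 0, 50, 50), inner=(10, 10, 60, 40))

    def test_frameless_geometry_rejected(self):
        with pytest.raises(ValueError, match="no frame"):
            FrameGeometry(outer=(0, 0, 50, 50), inner=(0, 0, 50, 50))

    def test_area_percent_strictly_between_0_and_100(self):
        geom = FrameGeometry(outer=(0, 0, 40, 30), inner=(1, 1, 39, 29))
        assert 0.0 < frame_area_percent(geom) < 100.0


class TestSpecificComplexity:
    # Printed per-painting values: gray-fill frame complexity, frame area
    # percent, and the specific complexity they imply, to one decimal.
    @pytest.mark.parametrize("fill,area,expected", [
        (4.62, 26.1, 17.7),
        (6.85, 50.6, 13.5),
        (2.92, 27.4, 10.7),
        (2.17, 65.5, 3.3),
    ])
    def test_reference_worked_examples(self, fill, area, expected):
        assert round(specific_frame_complexity(fill, area), 1) == expected

    def test_zero_fill_gives_zero(self):
        assert specific_frame_complexity(0.0, 40.0) == 0.0

    def test_zero_area_undefined(self):
        assert np.isnan(specific_frame_complexity(3.0, 0.0))

    def test_never_below_fill_value(self):
        # area fraction <= 1, so dividing by it can only increase the value
        assert specific_frame_complexity(2.5, 99.0) >= 2.5


class TestDifferenceEstimator:
    def test_identical_images_give_zero(self, rng):
        img = RasterImage(rng.random((64, 64, 3)))
        sip = measure_image(img)
        assert frame_complexity_difference(sip, sip) == 0.0

    def test_budget_mismatch_rejected(self, rng):
        img = RasterImage(rng.random((400, 400, 3)))
        a = measure_image(img, budget=40_000)
        b = measure_image(img, budget=90_000)
        with pytest.raises(ValueError, match="budgets differ"):
            frame_complexity_difference(a, b)

    def test_frame_raises_complexity_of_synthetic_pair(self, default_family):
        p = measure_image(default_family["P"])
        pwf = measure_image(default_family["PwF"])
        assert frame_complexity_difference(p, pwf) > 0.0


def _uniform_lab_pwf(L_frame, h=60, w=80, band=10):
    px = np.zeros((h, w, 3))
    px[:, :, 0] = L_frame
    geom = FrameGeometry(outer=(0, 0, w, h), inner=(band, band, w - band, h - band))
    return RasterImage(px, "Lab"), geom


def _naive_l_complexity(L):
    """Independent oracle: mean gradient magnitude of an L plane by explicit
    per-pixel centered/one-sided differences."""
    h, w = L.shape
    total = 0.0
    for r in range(h):
        for c in range(w):
            gx = (
                L[r, 1] - L[r, 0] if c == 0
                else L[r, -1] - L[r, -2] if c == w - 1
                else (L[r, c + 1] - L[r, c - 1]) / 2
            )
            gy = (
                L[1, c] - L[0, c] if r == 0
                else L[-1, c] - L[-2, c] if r == h - 1
                else (L[r + 1, c] - L[r - 1, c]) / 2
            )
            total += np.hypot(gx, gy)
    return total / (h * w)


class TestFillEstimator:
    def test_everything_uniform_gives_zero(self):
        img, geom = _uniform_lab_pwf(50.0)
        assert frame_complexity_fill(img, geom, 50, budget=None) == 0.0

    def test_uniform_band_matches_border_edge_oracle(self):
        # Uniform L=70 band with a gray fill: the only gradients are the
        # step at the inner border; compare against the per-pixel oracle.
        img, geom = _uniform_lab_pwf(70.0)
        filled = fill_inner_rectangle(img, geom, 50)
        expected = _naive_l_complexity(filled.pixels[:, :, 0])
        got = frame_complexity_fill(img, geom, 50, budget=None)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got > 0.0

    def test_gray_fill_smallest_on_intermediate_luminance_frames(self):
        # Frames of intermediate luminance contrast least with the gray
        # rectangle, so on average the 50 % fill yields the lowest value.
        vals = {0: [], 50: [], 100: []}
        for seed in range(5):
            fam = compose_family(SceneSpec(
                seed=seed,
                frame=FrameParams(width_frac=0.15),
            ))
            for lum in vals:
                vals[lum].append(frame_complexity_fill(
                    fam["PwF"], fam["geometry"], lum, budget=None))
        assert np.mean(vals[50]) < np.mean(vals[0])
        assert np.mean(vals[50]) < np.mean(vals[100])

    def test_fill_luminance_sensitivity_bounded(self, default_family):
        f = {
            lum: frame_complexity_fill(
                default_family["PwF"], default_family["geometry"], lum, budget=None
            )
            for lum in (0, 50, 100)
        }
        assert abs(f[0] - f[100]) < 0.25 * f[50]

    def test_specific_complexity_stable_under_crop_rescaling(self, default_family):
        # Measured at a common budget, the specific frame complexity should
        # not depend on the resolution the PwF crop arrived at.
        pwf, geom = default_family["PwF"], default_family["geometry"]
        budget = 60_000
        v1 = specific_frame_complexity(
            frame_complexity_fill(pwf, geom, 50, budget=budget),
            frame_area_percent(geom),
        )
        up = RasterImage(
            skresize(pwf.pixels, (pwf.height * 3 // 2, pwf.width * 3 // 2),
                     order=3, anti_aliasing=False, preserve_range=True).clip(0, 1),
            "sRGB",
        )
        geom_up = geom.scaled(up.width / pwf.width, up.height / pwf.height)
        v2 = specific_frame_complexity(
            frame_complexity_fill(up, geom_up, 50, budget=budget),
            frame_area_percent(geom_up),
        )
        assert v2 == pytest.approx(v1, rel=0.1)

    def test_geometry_outside_image_rejected(self, rng):
        img = RasterImage(rng.random((40, 40, 3)))
        geom = FrameGeometry(outer=(0, 0, 60, 60), inner=(10, 10, 50, 50))
        with pytest.raises(ValueError, match="exceeds"):
            frame_complexity_fill(img, geom, 50, budget=None)


class TestAnalyzeManifest:
    def test_empty_manifest(self):
        per_image, pairs = analyze_manifest([])
        assert per_image.empty and pairs.empty

    def test_synthetic_family_produces_all_rows(self, default_family):
        records = [
            SceneRecord(id="fam0", group="g", category=cat,
                        image=default_family[cat],
                        geometry=default_family["geometry"] if cat == "PwF" else None)
            for cat in ("P", "PwF", "PwF_S", "MSc")
        ]
        per_image, pairs = analyze_manifest(records, budget=None)
        assert len(per_image) == 4
        assert set(per_image.category) == {"P", "PwF", "PwF_S", "MSc"}
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row.frame_area_percent == pytest.approx(
            frame_area_percent(default_family["geometry"]))
        assert row.delta_complexity is not None
        assert row.specific_frame_complexity > row.fill_complexity_50

    def test_unreadable_file_skipped_with_error(self, caplog, default_family):
        records = [
            SceneRecord(id="ok", group="g", category="P", image=default_family["P"]),
            SceneRecord(id="bad", group="g", category="P", path="/nonexistent.png"),
        ]
        with caplog.at_level(logging.ERROR):
            per_image, _ = analyze_manifest(records, budget=None)
        assert len(per_image) == 1
        assert any("bad" in r.message for r in caplog.records)

    def test_missing_pair_member_warns_and_skips(self, caplog, default_family):
        records = [
            SceneRecord(id="solo", group="g", category="PwF",
                        image=default_family["PwF"],
                        geometry=default_family["geometry"]),
        ]
        with caplog.at_level(logging.WARNING):
            per_image, pairs = analyze_manifest(records, budget=None)
        assert len(per_image) == 1
        assert pairs.iloc[0].delta_complexity is None

    def test_write_batch_roundtrip(self, tmp_path):
        manifest = write_batch(tmp_path, families=1, seed=3, groups=("modern",))
        records = read_manifest(manifest)
        assert len(records) == 4
        pwf = [r for r in records if r.category == "PwF"][0]
        assert pwf.geometry is not None
        per_image, pairs = analyze_manifest(records, budget=None)
        assert len(per_image) == 4 and len(pairs) == 1
        # PNG quantization perturbs pixels, not the geometry bookkeeping
        assert pairs.iloc[0].frame_area_percent == pytest.approx(
            frame_area_percent(pwf.geometry))
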