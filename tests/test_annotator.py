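"""Score arithmetic, history construction and drop-based mask selection."""

import numpy as np
import pytest

from greenpoly.annotator import (
    AnnotatorParams,
    EmptyHistoryError,
    IterationRecord,
    SegmentationHistory,
    annotate_box,
    build_history,
    compute_k_area,
    compute_k_shape,
    compute_score,
    select_best_iteration,
)
from greenpoly.evaluation import contour_to_mask, mask_iou
from greenpoly.scenes import SceneConfig, generate_scene
from greenpoly.voc import LabeledBox, crop_region

from conftest import flat_hsv_crop


class TestCoefficients:
    def test_k_area_ratio(self):
        assert compute_k_area(500, 1000) == 0.5
        assert compute_k_area(850, 850) == 1.0

    def test_k_area_first_stored_iteration_is_one(self):
        assert compute_k_area(700, None) == 1.0

    def test_k_area_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            compute_k_area(0, 10)
        with pytest.raises(ValueError):
            compute_k_area(10, 0)

    def test_k_shape_rect_over_crop(self):
        assert compute_k_shape((50, 20), (100, 40)) == 0.25
        assert compute_k_shape((100, 40), (100, 40)) == 1.0
        assert compute_k_shape((1, 1), (100, 100)) == 0.0001

    def test_k_shape_rejects_zero_crop(self):
        with pytest.raises(ValueError):
            compute_k_shape((1, 1), (0, 10))

    def test_score_weighted_sum(self):
        p = AnnotatorParams()
        assert compute_score(1.0, 1.0, p) == pytest.approx(1.0)
        assert compute_score(0.5, 0.25, p) == pytest.approx(0.425)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            AnnotatorParams(w_area=0.8, w_shape=0.3)
        with pytest.raises(ValueError):
            AnnotatorParams(drop_fraction=0.0)
        with pytest.raises(ValueError):
            AnnotatorParams(h_start=80, n_bands=16, h_top=85)


def _history_from_scores(scores):
    dummy_mask = np.ones((1, 1), dtype=bool)
    records = [
        IterationRecord(
            h_low=22 + i, mask=dummy_mask, contour=None, area=1.0,
            k_area=1.0, k_shape=1.0, score=s,
        )
        for i, s in enumerate(scores)
    ]
    return SegmentationHistory(records=records)


class TestSelectBestIteration:
    def test_first_significant_drop(self):
        h = _history_from_scores([1.00, 0.97, 0.95, 0.94, 0.50, 0.45])
        # range 0.55, threshold 0.11; first qualifying drop is 0.94 -> 0.50
        assert select_best_iteration(h, 0.2) == 3

    def test_constant_scores_fall_back_to_last(self):
        assert select_best_iteration(_history_from_scores([0.8, 0.8, 0.8]), 0.2) == 2

    def test_single_record(self):
        assert select_best_iteration(_history_from_scores([0.42]), 0.2) == 0

    def test_empty_history_raises(self):
        with pytest.raises(EmptyHistoryError):
            select_best_iteration(SegmentationHistory(), 0.2)

    def test_agrees_with_exhaustive_scan_on_random_sequences(self):
        """Independent oracle: literal scan over consecutive pairs."""

        def oracle(scores, frac):
            r = max(scores) - min(scores)
            if r > 0:
                for j in range(1, len(scores)):
                    if scores[j - 1] - scores[j] > frac * r:
                        return j - 1
            return len(scores) - 1

        rng = np.random.default_rng(123)
        for trial in range(1200):
            n = int(rng.integers(1, 17))
            kind = trial % 4
            if kind == 0:
                scores = list(rng.uniform(0, 1, n))
            elif kind == 1:  # constant
                scores = [float(rng.uniform())] * n
            elif kind == 2:  # monotone gentle decline, often no drop
                scores = list(np.linspace(1.0, rng.uniform(0.5, 1.0), n))
            else:  # step function
                scores = [1.0] * n
                if n > 1:
                    k = int(rng.integers(1, n))
                    scores[k:] = [float(rng.uniform(0, 0.5))] * (n - k)
            frac = float(rng.uniform(0.05, 0.9))
            assert select_best_iteration(_history_from_scores(scores), frac) == oracle(scores, frac)

    def test_weight_extremes_can_disagree(self):
        """With weights (1,0) selection follows area dynamics; with (0,1) rect
        dynamics — a history where area collapses but the rect holds (or vice
        versa) is selected differently."""
        k_areas = [1.0, 1.0, 0.3, 1.0, 1.0]  # sharp area loss at i=2
        k_shapes = [1.0, 1.0, 1.0, 1.0, 0.3]  # sharp rect loss at i=4
        area_only = _history_from_scores(k_areas)
        shape_only = _history_from_scores(k_shapes)
        assert select_best_iteration(area_only, 0.2) == 1
        assert select_best_iteration(shape_only, 0.2) == 3


class TestBuildHistory:
    def test_uniform_green_crop_all_bands_score_one(self, green_crop):
        h = build_history(green_crop, AnnotatorParams())
        assert len(h) == 16
        for r in h.records:
            assert r.k_area == pytest.approx(1.0)
            assert r.k_shape == pytest.approx(1.0)
            assert r.score == pytest.approx(1.0)
        assert [r.h_low for r in h.records] == list(range(22, 38))

    def test_soil_crop_yields_empty_history(self, soil_crop):
        assert len(build_history(soil_crop, AnnotatorParams())) == 0

    def test_hue_30_crop_stores_only_lower_bands(self):
        crop = flat_hsv_crop(30, 200, 150)
        h = build_history(crop, AnnotatorParams())
        assert [r.h_low for r in h.records] == list(range(22, 31))

    def test_score_recomposition_within_1e9(self):
        scene = generate_scene(SceneConfig(seed=9, shadow_strength=0.5, stone_probability=0.7))
        p = AnnotatorParams()
        crop = crop_region(scene.image, scene.objects[0].box)
        h = build_history(crop, p)
        assert len(h) > 0
        for r in h.records:
            assert r.score == pytest.approx(p.w_area * r.k_area + p.w_shape * r.k_shape, abs=1e-9)

    def test_skipped_bands_do_not_update_predecessor_area(self):
        # two-tone crop: a large hue-25 region and a small hue-60 one; the
        # hue-25 region drops out at h_low=26 and bands 26..37 see only the
        # small region, whose k_area must be computed against the last
        # STORED area, not against a skipped band
        crop = flat_hsv_crop(25, 200, 150, shape=(40, 40))
        crop[:10, :10] = flat_hsv_crop(60, 200, 150, shape=(10, 10))
        h = build_history(crop, AnnotatorParams())
        h_lows = [r.h_low for r in h.records]
        assert h_lows == list(range(22, 38))  # hue-60 blob keeps all bands alive
        areas = [r.area for r in h.records]
        k_areas = [r.k_area for r in h.records]
        for i in range(1, len(h)):
            assert k_areas[i] == pytest.approx(areas[i] / areas[i - 1])

    def test_determinism(self):
        scene = generate_scene(SceneConfig(seed=17, shadow_strength=0.5, stone_probability=0.7))
        crop = crop_region(scene.image, scene.objects[0].box)
        h1 = build_history(crop)
        h2 = build_history(crop)
        assert len(h1) == len(h2)
        for a, b in zip(h1.records, h2.records):
            assert a.score == b.score and a.area == b.area
            np.testing.assert_array_equal(a.mask, b.mask)


class TestAnnotateBox:
    def test_soil_only_box_returns_none(self, soil_crop):
        box = LabeledBox("weed", 0, 0, 40, 40)
        assert annotate_box(soil_crop, box) is None

    def test_all_green_crop_recovers_full_box(self, green_crop):
        box = LabeledBox("crop", 0, 0, 40, 40)
        contour = annotate_box(green_crop, box)
        filled = contour_to_mask(contour, (40, 40))
        assert mask_iou(filled, np.ones((40, 40), dtype=bool)) > 95

    def test_single_plant_recovered_against_ground_truth(self):
        scene = generate_scene(SceneConfig(seed=21, n_plants=1))
        obj = scene.objects[0]
        contour = annotate_box(scene.image, obj.box)
        auto = contour_to_mask(contour, (obj.box.height, obj.box.width))
        ref = crop_region(obj.mask, obj.box)
        assert mask_iou(auto, ref) >= 90
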