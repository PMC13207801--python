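"""Mask-agreement metrics (IoU, Dice), batch evaluation, and the weight
sweep used to choose the score weights w_area / w_shape.

Metrics are reported in percent, matching the convention of segmentation
benchmarks. Per pair, DSC = 2*IoU/(1+IoU) in fraction form; the identity
does not survive averaging, so means are computed from per-pair values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask

from .annotator import AnnotatorParams, annotate_box
from .color import Contour
from .voc import crop_region

__all__ = [
    "EvalResult",
    "mask_iou",
    "mask_dsc",
    "evaluate_dataset",
    "contour_to_mask",
    "annotate_scene",
    "evaluate_scenes",
    "weight_sweep",
    "match_polygons_to_refs",
]

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    per_pair: list[tuple[float, float]]
    mean_iou: float
    mean_dsc: float
    n: int


def _check_pair(auto: np.ndarray, ref: np.ndarray) -> tuple[float, float, float]:
    if auto.shape != ref.shape:
        raise ValueError(f"mask shape mismatch: {auto.shape} vs {ref.shape}")
    a = auto.astype(bool)
    m = ref.astype(bool)
    inter = float(np.logical_and(a, m).sum())
    return inter, float(a.sum()), float(m.sum())


def mask_iou(auto: np.ndarray, ref: np.ndarray) -> float:
    """Intersection-over-union of two equal-shape binary masks, percent."""
    inter, na, nm = _check_pair(auto, ref)
    union = na + nm - inter
    if union == 0:
        logger.warning("both masks empty: IoU defined as 100")
        return 100.0
    return 100.0 * inter / union


def mask_dsc(auto: np.ndarray, ref: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks, percent."""
    inter, na, nm = _check_pair(auto, ref)
    total = na + nm
    if total == 0:
        logger.warning("both masks empty: DSC defined as 100")
        return 100.0
    return 100.0 * 2.0 * inter / total


def evaluate_dataset(auto_masks: list[np.ndarray], ref_masks: list[np.ndarray]) -> EvalResult:
    """Per-pair IoU/DSC plus arithmetic means over all pairs."""
    if len(auto_masks) != len(ref_masks):
        raise ValueError("auto and reference mask lists differ in length")
    if not auto_masks:
        raise ValueError("nothing to evaluate")
    per_pair = [(mask_iou(a, m), mask_dsc(a, m)) for a, m in zip(auto_masks, ref_masks)]
    ious, dscs = zip(*per_pair)
    return EvalResult(
        per_pair=per_pair,
        mean_iou=float(np.mean(ious)),
        mean_dsc=float(np.mean(dscs)),
        n=len(per_pair),
    )


def contour_to_mask(contour: Contour | np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a contour (or raw (x, y) vertex array) as a filled mask."""
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, dtype=float)
    return polygon2mask(shape, pts[:, ::-1])  # (x, y) -> (row, col)


def annotate_scene(scene, params: AnnotatorParams | None = None) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Run the annotator on every object of a synthetic scene.

    Returns crop-local (auto_mask, reference_mask) lists, one entry per
    object. A box the annotator cannot segment contributes an empty
    automatic mask, which scores 0 against its non-empty reference.
    """
    params = params or AnnotatorParams()
    auto_masks, ref_masks = [], []
    for obj in scene.objects:
        box = obj.box
        crop_shape = (box.height, box.width)
        contour = annotate_box(scene.image, box, params)
        if contour is None:
            auto = np.zeros(crop_shape, dtype=bool)
        else:
            auto = contour_to_mask(contour, crop_shape)
        auto_masks.append(auto)
        ref_masks.append(crop_region(obj.mask, box).astype(bool))
    return auto_masks, ref_masks


def evaluate_scenes(scenes, params: AnnotatorParams | None = None) -> EvalResult:
    """Annotate every object of every scene and score against ground truth."""
    auto_all, ref_all = [], []
    for scene in scenes:
        a, r = annotate_scene(scene, params)
        auto_all.extend(a)
        ref_all.extend(r)
    return evaluate_dataset(auto_all, ref_all)


def weight_sweep(
    scenes,
    weight_grid: list[tuple[float, float]] | None = None,
    params: AnnotatorParams | None = None,
) -> pd.DataFrame:
    """Re-run the full annotator for each (w_area, w_shape) pair.

    The default grid is the 11 pairs (1.0, 0.0) .. (0.0, 1.0) in steps of
    0.1. Returns one row per pair with the mean IoU/DSC over all objects.
    """
    params = params or AnnotatorParams()
    if weight_grid is None:
        weight_grid = [(round(1.0 - i / 10, 1), round(i / 10, 1)) for i in range(11)]
    for wa, ws in weight_grid:
        if abs(wa + ws - 1.0) > 1e-9:
            raise ValueError(f"weights ({wa}, {ws}) must sum to 1")
    rows = []
    for wa, ws in weight_grid:
        result = evaluate_scenes(scenes, replace(params, w_area=wa, w_shape=ws))
        rows.append((wa, ws, result.mean_iou, result.mean_dsc))
        logger.debug("sweep w_area=%.1f: IoU=%.2f DSC=%.2f", wa, result.mean_iou, result.mean_dsc)
    return pd.DataFrame(rows, columns=["w_area", "w_shape", "mean_iou", "mean_dsc"])


def match_polygons_to_refs(
    polygon_masks: list[np.ndarray],
    ref_masks: list[np.ndarray],
) -> list[np.ndarray]:
    """Pair each reference mask with the best-IoU polygon mask.

    Used when evaluating emitted label files, where rejected boxes leave no
    polygon and positional pairing would misalign. A reference with no
    overlapping polygon gets an empty automatic mask.
    """
    matched = []
    for ref in ref_masks:
        best_iou, best = -1.0, None
        for pm in polygon_masks:
            iou = mask_iou(pm, ref) if pm.shape == ref.shape else -1.0
            if iou > best_iou:
                best_iou, best = iou, pm
        matched.append(best if best is not None else np.zeros_like(ref))
    return matched
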