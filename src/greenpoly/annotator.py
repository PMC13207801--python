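"""Iterative hue-range narrowing with integral contour-quality scoring.

This is the heart of the package. Given a crop containing one plant, the
lower hue bound is raised one half-degree step at a time while the upper
bound stays fixed, producing a nested family of binary masks. Each stored
iteration is scored by

    Score = w_area * k_area + w_shape * k_shape

where ``k_area = S_i / S_{i-1}`` is the area ratio of the principal contour
between successive stored iterations (1 for the first), and
``k_shape = (W_contour * H_contour) / (W * H)`` compares the contour's
tight bounding rectangle with the crop. A sharp fall in k_area means large
parts of the object were lost; k_shape additionally catches the loss of
elongated structures (leaves) that change the bounding rectangle more than
the area. The mask kept is the one from the last stable iteration before
the first Score drop exceeding a fraction of the observed score range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .color import Contour, HsvBand, hue_band_mask, largest_contour, refine_mask, rgb_to_hsv
from .voc import LabeledBox, crop_region

__all__ = [
    "AnnotatorParams",
    "IterationRecord",
    "SegmentationHistory",
    "EmptyHistoryError",
    "compute_k_area",
    "compute_k_shape",
    "compute_score",
    "build_history",
    "select_best_iteration",
    "annotate_box",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotatorParams:
    """Tunable parameters of the iterative annotator.

    Defaults are the reference configuration: hue window starts at [22, 85]
    and the lower bound rises by 1 for 16 iterations; S in [20, 255] and V
    in [20, 240] exclude deep shadow, near-achromatic soil and blown-out
    highlights; contours under 50 px are noise; weights 0.7/0.3 favour area
    stability over rectangle dynamics; a score drop exceeding 20% of the
    score range flags degradation; the polygon tolerance is 0.0015 of the
    contour perimeter.
    """

    h_start: int = 22
    h_top: int = 85
    n_bands: int = 16
    s_bounds: tuple[int, int] = (20, 255)
    v_bounds: tuple[int, int] = (20, 240)
    min_area: float = 50.0
    w_area: float = 0.7
    w_shape: float = 0.3
    drop_fraction: float = 0.2
    epsilon_factor: float = 0.0015

    def __post_init__(self) -> None:
        if abs(self.w_area + self.w_shape - 1.0) > 1e-9:
            raise ValueError("w_area + w_shape must equal 1")
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if self.h_start + self.n_bands - 1 > self.h_top:
            raise ValueError("hue bands exceed h_top")

    def band(self, i: int) -> HsvBand:
        """Hue band of iteration ``i``: [h_start + i, h_top] with fixed S/V."""
        return HsvBand(
            h_low=self.h_start + i,
            h_high=self.h_top,
            s_low=self.s_bounds[0],
            s_high=self.s_bounds[1],
            v_low=self.v_bounds[0],
            v_high=self.v_bounds[1],
        )


@dataclass(frozen=True)
class IterationRecord:
    h_low: int
    mask: np.ndarray
    contour: Contour
    area: float
    k_area: float
    k_shape: float
    score: float


@dataclass
class SegmentationHistory:
    """Stored iterations only — bands skipped for want of a contour are absent."""

    records: list[IterationRecord] = field(default_factory=list)

    @property
    def scores(self) -> list[float]:
        return [r.score for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, idx: int) -> IterationRecord:
        return self.records[idx]


class EmptyHistoryError(ValueError):
    """No band produced a usable contour; nothing to annotate."""


def compute_k_area(area_now: float, area_prev: float | None) -> float:
    """Area-change coefficient between successive stored iterations.

    The first stored iteration has no predecessor and scores 1 by
    definition.
    """
    if area_now <= 0:
        raise ValueError("area_now must be positive")
    if area_prev is None:
        return 1.0
    if area_prev <= 0:
        raise ValueError("area_prev must be positive")
    return area_now / area_prev


def compute_k_shape(contour_rect: tuple[float, float], crop_dims: tuple[float, float]) -> float:
    """Contour bounding-rectangle area over crop area."""
    w_c, h_c = contour_rect
    w, h = crop_dims
    if w <= 0 or h <= 0:
        raise ValueError("crop dimensions must be positive")
    return (h_c * w_c) / (h * w)


def compute_score(k_area: float, k_shape: float, params: AnnotatorParams) -> float:
    """Integral mask-quality score: weighted sum of the two coefficients."""
    return params.w_area * k_area + params.w_shape * k_shape


def build_history(crop: np.ndarray, params: AnnotatorParams | None = None) -> SegmentationHistory:
    """Run the full band sweep on one crop and record every scored iteration.

    Bands whose refined mask has no contour of at least ``min_area`` pixels
    are skipped and do not update the predecessor area used by k_area.
    """
    params = params or AnnotatorParams()
    hsv = rgb_to_hsv(crop)
    crop_h, crop_w = crop.shape[:2]
    history = SegmentationHistory()
    prev_area: float | None = None
    for i in range(params.n_bands):
        band = params.band(i)
        mask = refine_mask(hue_band_mask(hsv, band))
        contour = largest_contour(mask, min_area=params.min_area)
        if contour is None:
            logger.debug("band h_low=%d: skipped (no contour >= %g px)", band.h_low, params.min_area)
            continue
        k_area = compute_k_area(contour.area, prev_area)
        k_shape = compute_k_shape(contour.rect[2:], (crop_w, crop_h))
        score = compute_score(k_area, k_shape, params)
        prev_area = contour.area
        history.records.append(
            IterationRecord(
                h_low=band.h_low,
                mask=mask,
                contour=contour,
                area=contour.area,
                k_area=k_area,
                k_shape=k_shape,
                score=score,
            )
        )
        logger.debug(
            "band h_low=%d: area=%g k_area=%.4f k_shape=%.4f score=%.4f",
            band.h_low, contour.area, k_area, k_shape, score,
        )
    return history


def select_best_iteration(history: SegmentationHistory, drop_fraction: float = 0.2) -> int:
    """Index of the last stable iteration before the first significant drop.

    A drop between consecutive stored records is significant when it
    exceeds ``drop_fraction`` times the score range (max - min over the
    whole history). If the range is zero or no drop qualifies, the last
    index is returned: the narrowest band that stayed stable.
    """
    scores = history.scores
    if not scores:
        raise EmptyHistoryError("empty history: no annotation")
    score_range = max(scores) - min(scores)
    if score_range > 0:
        threshold = drop_fraction * score_range
        for j in range(1, len(scores)):
            if scores[j - 1] - scores[j] > threshold:
                logger.debug("significant drop at stored index %d; selecting %d", j, j - 1)
                return j - 1
    return len(scores) - 1


def annotate_box(
    image: np.ndarray,
    box: LabeledBox,
    params: AnnotatorParams | None = None,
) -> Contour | None:
    """Segment the object inside ``box`` and return its principal contour.

    The contour is in crop-local coordinates. Returns ``None`` when no hue
    band yields a usable mask (e.g. a box containing only soil).
    """
    params = params or AnnotatorParams()
    crop = crop_region(image, box)
    history = build_history(crop, params)
    if len(history) == 0:
        return None
    best = select_best_iteration(history, params.drop_fraction)
    logger.debug("selected stored iteration %d (h_low=%d)", best, history[best].h_low)
    return history[best].contour
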