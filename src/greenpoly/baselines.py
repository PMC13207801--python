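"""Classical segmentation baselines: fixed HSV threshold, Otsu, adaptive
threshold, and K-means clustering.

Each baseline maps an RGB crop to a binary mask, making them drop-in
alternatives to the iterative annotator in the evaluation harness. Raw
binarization has no notion of vegetation, so where a method yields two
classes the one whose mean hue is closest to the green band center is taken
as foreground.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from .color import HsvBand, hue_band_mask, refine_mask, rgb_to_hsv

__all__ = [
    "BaselineConfig",
    "segment_fixed_hsv",
    "segment_otsu",
    "segment_adaptive",
    "segment_kmeans",
    "segment",
    "BASELINE_METHODS",
]

logger = logging.getLogger(__name__)

#: Center of the default green hue band, used for foreground-class selection.
GREEN_HUE_CENTER = (22 + 85) / 2


@dataclass(frozen=True)
class BaselineConfig:
    method: str = "fixed_hsv"
    fixed_band: HsvBand = field(default_factory=lambda: HsvBand(22, 85, 20, 255, 20, 240))
    adaptive_block: int = 31
    adaptive_offset: float = 5.0
    kmeans_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adaptive_block < 3 or self.adaptive_block % 2 == 0:
            raise ValueError("adaptive_block must be odd and >= 3")
        if self.kmeans_k < 2:
            raise ValueError("kmeans_k must be >= 2")


def _luminance(crop: np.ndarray) -> np.ndarray:
    rgb = crop.astype(np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def _hue_distance(hue: np.ndarray | float, center: float = GREEN_HUE_CENTER) -> np.ndarray | float:
    """Circular distance on the 0-179 hue wheel."""
    d = np.abs(np.asarray(hue, dtype=float) - center)
    return np.minimum(d, 180.0 - d)


def _greener_class(hsv: np.ndarray, binary: np.ndarray) -> np.ndarray:
    """Pick whichever side of a binarization is closer to green in mean hue."""
    hue = hsv[..., 0].astype(float)
    candidates = []
    for side in (binary, ~binary):
        if side.any():
            candidates.append((float(_hue_distance(hue[side].mean())), side))
    if not candidates:
        return np.zeros_like(binary)
    return min(candidates, key=lambda c: c[0])[1]


def segment_fixed_hsv(crop: np.ndarray, config: BaselineConfig | None = None) -> np.ndarray:
    """Single-shot HSV band threshold followed by morphological refinement.

    Identical to iteration 0 of the iterative annotator: the band never
    narrows, so background in the wide hue window stays in the mask.
    """
    config = config or BaselineConfig()
    return refine_mask(hue_band_mask(rgb_to_hsv(crop), config.fixed_band))


def segment_otsu(crop: np.ndarray, config: BaselineConfig | None = None) -> np.ndarray:
    """Otsu global binarization of luminance, green-closest class foreground."""
    lum = _luminance(crop)
    if np.ptp(lum) == 0:
        logger.info("constant-luminance crop: Otsu yields empty mask")
        return np.zeros(crop.shape[:2], dtype=bool)
    t = threshold_otsu(lum)
    return _greener_class(rgb_to_hsv(crop), lum > t)


def segment_adaptive(crop: np.ndarray, config: BaselineConfig | None = None) -> np.ndarray:
    """Local-mean adaptive threshold of luminance.

    Per-pixel threshold is the mean over an ``adaptive_block`` window minus
    ``adaptive_offset``; the green-closest side of the binarization is the
    foreground. A constant-luminance crop carries no contrast to threshold
    and yields an empty mask (logged), mirroring the Otsu degenerate rule.
    """
    config = config or BaselineConfig()
    lum = _luminance(crop)
    if np.ptp(lum) == 0:
        logger.info("constant-luminance crop: adaptive threshold yields empty mask")
        return np.zeros(crop.shape[:2], dtype=bool)
    local_mean = ndi.uniform_filter(lum, size=config.adaptive_block, mode="reflect")
    return _greener_class(rgb_to_hsv(crop), lum > local_mean - config.adaptive_offset)


def segment_kmeans(crop: np.ndarray, config: BaselineConfig | None = None) -> np.ndarray:
    """K-means clustering in HSV space; greenest-centroid cluster foreground.

    Hue circularity is handled by embedding hue as a (cos, sin) pair; the
    clustering is deterministic for a given seed. If the crop has fewer
    distinct colors than k, the effective cluster count is reduced.
    """
    config = config or BaselineConfig()
    hsv = rgb_to_hsv(crop)
    angle = hsv[..., 0].astype(float) * 2.0 * np.pi / 180.0
    features = np.stack(
        [
            np.cos(angle),
            np.sin(angle),
            hsv[..., 1].astype(float) / 255.0,
            hsv[..., 2].astype(float) / 255.0,
        ],
        axis=-1,
    ).reshape(-1, 4)
    k = min(config.kmeans_k, len(np.unique(features, axis=0)))
    if k < 2:
        return np.ones(crop.shape[:2], dtype=bool)
    km = KMeans(n_clusters=k, n_init=3, random_state=config.seed)
    labels = km.fit_predict(features)
    centroid_hue = (
        np.degrees(np.arctan2(km.cluster_centers_[:, 1], km.cluster_centers_[:, 0])) / 2.0
    ) % 180.0
    occupied = np.unique(labels)
    greenest = occupied[np.argmin(_hue_distance(centroid_hue[occupied]))]
    return (labels == greenest).reshape(crop.shape[:2])


BASELINE_METHODS = {
    "fixed_hsv": segment_fixed_hsv,
    "otsu": segment_otsu,
    "adaptive": segment_adaptive,
    "kmeans": segment_kmeans,
}


def segment(crop: np.ndarray, config: BaselineConfig) -> np.ndarray:
    """Dispatch to the configured baseline method."""
    try:
        fn = BASELINE_METHODS[config.method]
    except KeyError:
        raise ValueError(f"unknown baseline method {config.method!r}") from None
    return fn(crop, config)
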