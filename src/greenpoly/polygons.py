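"""Contour simplification and YOLO segmentation-label export.

The selected contour is simplified with the Douglas-Peucker algorithm
(tolerance proportional to the contour perimeter), translated back into
full-image coordinates, and written as YOLO-seg label lines: class id
followed by the polygon vertices normalized to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .color import Contour
from .voc import LabeledBox

__all__ = [
    "PolygonAnnotation",
    "approximate_contour",
    "to_global_coords",
    "write_yolo_seg",
    "parse_yolo_seg",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PolygonAnnotation:
    """Closed polygon in full-image pixel coordinates (implicitly closed)."""

    class_id: int
    vertices: np.ndarray  # (N, 2) float, N >= 3

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")


def approximate_contour(contour: Contour, epsilon_factor: float = 0.0015) -> np.ndarray | None:
    """Douglas-Peucker simplification with eps = epsilon_factor * perimeter.

    Every original contour point is guaranteed to lie within eps of the
    simplified polyline. With ``epsilon_factor = 0`` all points are kept.
    Returns ``None`` if fewer than 3 distinct vertices survive.
    """
    pts = contour.points
    if len(pts) < 3:
        return None
    eps = epsilon_factor * contour.perimeter
    # approximate_polygon works on (row, col); flip, simplify, flip back
    simplified = measure.approximate_polygon(pts[:, ::-1], tolerance=eps)[:, ::-1]
    # drop the closing duplicate vertex if present
    if len(simplified) > 1 and np.allclose(simplified[0], simplified[-1]):
        simplified = simplified[:-1]
    if len(simplified) < 3:
        return None
    return simplified


def to_global_coords(
    vertices: np.ndarray,
    box: LabeledBox,
    image_dims: tuple[int, int],
) -> np.ndarray:
    """Translate crop-local vertices by the box origin and clamp to bounds.

    Clamping (rather than rejection) keeps polygons usable when boxes abut
    the image edge, which is common in field imagery.
    """
    width, height = image_dims
    out = np.asarray(vertices, dtype=float) + np.array([box.x_min, box.y_min], dtype=float)
    out[:, 0] = np.clip(out[:, 0], 0, width - 1)
    out[:, 1] = np.clip(out[:, 1], 0, height - 1)
    return out


def write_yolo_seg(
    annotations: list[PolygonAnnotation],
    image_dims: tuple[int, int],
) -> str:
    """Render annotations as YOLO-seg label text.

    One line per object: ``class_id x1 y1 x2 y2 ...`` with coordinates
    normalized by image width/height, fixed 6-decimal precision. Polygons
    with fewer than 3 vertices are skipped with a warning.
    """
    width, height = image_dims
    if width <= 0 or height <= 0:
        raise ValueError("image dimensions must be positive")
    lines = []
    for ann in annotations:
        if len(ann.vertices) < 3:
            logger.warning("skipping polygon with %d vertices", len(ann.vertices))
            continue
        coords = np.asarray(ann.vertices, dtype=float)
        norm = coords / np.array([width, height], dtype=float)
        norm = np.clip(norm, 0.0, 1.0)
        flat = " ".join(f"{v:.6f}" for v in norm.ravel())
        lines.append(f"{ann.class_id} {flat}")
    return "\n".join(lines) + ("\n" if lines else "")


def parse_yolo_seg(text: str, image_dims: tuple[int, int]) -> list[PolygonAnnotation]:
    """Parse YOLO-seg label text back into pixel-coordinate polygons."""
    width, height = image_dims
    annotations = []
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        class_id = int(parts[0])
        values = np.array(parts[1:], dtype=float).reshape(-1, 2)
        vertices = values * np.array([width, height], dtype=float)
        annotations.append(PolygonAnnotation(class_id=class_id, vertices=vertices))
    return annotations
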