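"""Pascal VOC bounding-box ingestion, cleaning and crop extraction.

Field-crop datasets such as LincolnBeet ship axis-aligned bounding boxes in
Pascal VOC XML. This module reads them, converts VOC's 1-based inclusive
pixel coordinates to the 0-based half-open convention used internally,
removes duplicated/degenerate boxes, and cuts per-object crops that feed the
color-segmentation pipeline.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "LabeledBox",
    "AnnotatedImage",
    "CleaningReport",
    "VocError",
    "VocRecordError",
    "read_voc_annotation",
    "write_voc_annotation",
    "clean_annotations",
    "crop_region",
    "box_iou",
    "load_class_map",
    "DEFAULT_CLASS_MAP",
]

#: Default label -> integer class id mapping for crop/weed datasets.
DEFAULT_CLASS_MAP = {"crop": 0, "weed": 1}


class VocError(ValueError):
    """Malformed VOC document (file-level problem)."""


class VocRecordError(VocError):
    """A single <object> record is unusable; carries the object index."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"object[{index}]: {message}")


@dataclass(frozen=True)
class LabeledBox:
    """Class-tagged axis-aligned box, 0-based half-open pixel coordinates."""

    class_name: str
    x_min: int
    y_min: int
    x_max: int
    y_max: int

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return max(self.width, 0) * max(self.height, 0)

    def is_degenerate(self) -> bool:
        return self.x_min >= self.x_max or self.y_min >= self.y_max

    def clamped(self, width: int, height: int) -> "LabeledBox":
        """Return a copy clamped to an image of the given dimensions."""
        return LabeledBox(
            self.class_name,
            min(max(self.x_min, 0), width),
            min(max(self.y_min, 0), height),
            min(max(self.x_max, 0), width),
            min(max(self.y_max, 0), height),
        )


@dataclass
class AnnotatedImage:
    image_id: str
    width: int
    height: int
    boxes: list[LabeledBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"non-positive image dims {self.width}x{self.height}")


@dataclass
class CleaningReport:
    """Bookkeeping for :func:`clean_annotations`; counts sum to n_input."""

    n_input: int = 0
    n_removed_duplicates: int = 0
    n_removed_degenerate: int = 0
    n_kept: int = 0


def box_iou(a: LabeledBox, b: LabeledBox) -> float:
    """Intersection-over-union of two axis-aligned boxes, as a fraction."""
    ix = max(0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _parse_int(obj_index: int, element, tag: str) -> int:
    node = element.find(tag)
    if node is None or node.text is None:
        raise VocRecordError(obj_index, f"missing <{tag}>")
    try:
        # VOC files in the wild sometimes carry "12.0"
        return int(round(float(node.text)))
    except ValueError as exc:
        raise VocRecordError(obj_index, f"non-numeric <{tag}>: {node.text!r}") from exc


def read_voc_annotation(
    source: str | Path,
    image_dims: tuple[int, int] | None = None,
) -> AnnotatedImage:
    """Parse a Pascal VOC XML annotation.

    Parameters
    ----------
    source:
        Path to an XML file, or the XML text itself.
    image_dims:
        ``(width, height)`` override; if omitted the document's ``<size>``
        element is required.

    VOC coordinates are 1-based inclusive; they are converted to 0-based
    half-open (``xmin-1 .. xmax``) and clamped to the image bounds. A box
    that is empty after conversion raises :class:`VocRecordError`.
    """
    path_name = "<string>"
    text = str(source)
    if not text.lstrip().startswith("<"):
        path_name = str(source)
        text = Path(source).read_text()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise VocError(f"malformed VOC XML in {path_name}: {exc}") from exc

    image_id = root.findtext("filename", default=path_name)
    image_id = Path(image_id).stem

    if image_dims is not None:
        width, height = image_dims
    else:
        size = root.find("size")
        if size is None:
            raise VocError(f"{path_name}: no <size> element and no image_dims given")
        width = int(size.findtext("width"))
        height = int(size.findtext("height"))

    boxes: list[LabeledBox] = []
    for idx, obj in enumerate(root.iter("object")):
        name = obj.findtext("name")
        if name is None:
            raise VocRecordError(idx, "missing <name>")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise VocRecordError(idx, "missing <bndbox>")
        xmin = _parse_int(idx, bnd, "xmin")
        ymin = _parse_int(idx, bnd, "ymin")
        xmax = _parse_int(idx, bnd, "xmax")
        ymax = _parse_int(idx, bnd, "ymax")
        if xmax <= xmin or ymax <= ymin:
            raise VocRecordError(idx, f"degenerate box {(xmin, ymin, xmax, ymax)}")
        box = LabeledBox(name, xmin - 1, ymin - 1, xmax, ymax).clamped(width, height)
        if box.is_degenerate():
            raise VocRecordError(idx, f"box outside image {(xmin, ymin, xmax, ymax)}")
        boxes.append(box)

    return AnnotatedImage(image_id=image_id, width=width, height=height, boxes=boxes)


def write_voc_annotation(annotated: AnnotatedImage, path: str | Path | None = None) -> str:
    """Serialize to VOC XML (inverse coordinate conversion of the reader)."""
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = f"{annotated.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(annotated.width)
    ET.SubElement(size, "height").text = str(annotated.height)
    ET.SubElement(size, "depth").text = "3"
    for box in annotated.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = box.class_name
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(box.x_min + 1)
        ET.SubElement(bnd, "ymin").text = str(box.y_min + 1)
        ET.SubElement(bnd, "xmax").text = str(box.x_max)
        ET.SubElement(bnd, "ymax").text = str(box.y_max)
    ET.indent(root)
    text = ET.tostring(root, encoding="unicode") + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def clean_annotations(
    boxes: list[LabeledBox],
    duplicate_iou_threshold: float = 0.9,
) -> tuple[list[LabeledBox], CleaningReport]:
    """Drop degenerate boxes and near-identical same-class duplicates.

    Among same-class boxes whose pairwise IoU reaches the threshold, the
    first in input order survives. Mis-classified objects are *not* touched:
    that correction needs human judgment and is out of scope here.
    """
    if not 0 < duplicate_iou_threshold <= 1:
        raise ValueError("duplicate_iou_threshold must be in (0, 1]")
    report = CleaningReport(n_input=len(boxes))
    kept: list[LabeledBox] = []
    for box in boxes:
        if box.is_degenerate():
            report.n_removed_degenerate += 1
            continue
        dup = any(
            k.class_name == box.class_name and box_iou(k, box) >= duplicate_iou_threshold
            for k in kept
        )
        if dup:
            report.n_removed_duplicates += 1
        else:
            kept.append(box)
    report.n_kept = len(kept)
    return kept, report


def crop_region(image: np.ndarray, box: LabeledBox) -> np.ndarray:
    """Extract the pixels of ``box`` from an ``(H, W, 3)`` image."""
    h, w = image.shape[:2]
    if box.x_min < 0 or box.y_min < 0 or box.x_max > w or box.y_max > h:
        raise IndexError(f"box {box} outside image {w}x{h}")
    if box.is_degenerate():
        raise ValueError(f"degenerate box {box}")
    return image[box.y_min : box.y_max, box.x_min : box.x_max].copy()


def load_class_map(path: str | Path | None = None) -> dict[str, int]:
    """Label -> class id map from a YAML/JSON file; defaults to crop/weed."""
    if path is None:
        return dict(DEFAULT_CLASS_MAP)
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of label -> class id")
    return {str(k): int(v) for k, v in data.items()}
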