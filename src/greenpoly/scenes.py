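"""Seeded generator of synthetic field-crop scenes with exact ground truth.

Scenes emulate the interference conditions of real field imagery of
early-stage sugar beet and weeds: green plant rosettes built from
overlapping elongated leaf lobes, textured brown/grey soil, multiplicative
shadow darkening on parts of the foliage, and occasional bright,
weakly-saturated stones whose hue sits just inside the wide end of the
green detection band. The generator provides the per-object ground-truth
masks and tight bounding boxes that make every pipeline stage testable
offline; it makes no attempt at photorealism.

Colors are composed in HSV (H 0-179, S/V 0-255) and converted to RGB at
the end, so the hue statistics of each surface class are controlled
exactly (up to uint8 round-trip quantization, which the sampling margins
absorb).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .color import hsv_to_rgb, rgb_to_hsv
from .voc import AnnotatedImage, LabeledBox, write_voc_annotation

__all__ = ["SceneConfig", "SceneObject", "SyntheticScene", "generate_scene", "generate_dataset"]

#: Soil tones: browns and greys. Hues land below the H=22 floor of the green
#: band or are too desaturated to pass the S >= 20 gate.
DEFAULT_SOIL_PALETTE = (
    (118, 85, 58),   # mid brown
    (96, 70, 50),    # dark brown
    (139, 108, 78),  # light brown
    (120, 112, 104), # warm grey
    (94, 90, 86),    # dark grey
)


@dataclass(frozen=True)
class SceneConfig:
    width: int = 256
    height: int = 256
    n_plants: int = 3
    leaf_lobes: tuple[int, int] = (4, 8)
    plant_hue_range: tuple[int, int] = (35, 75)
    soil_palette: tuple[tuple[int, int, int], ...] = DEFAULT_SOIL_PALETTE
    shadow_strength: float = 0.0
    stone_probability: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.plant_hue_range
        if not (0 <= lo <= hi <= 179):
            raise ValueError("plant_hue_range must lie within [0, 179]")
        for name in ("shadow_strength", "stone_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SceneObject:
    class_name: str
    box: LabeledBox
    mask: np.ndarray  # full-image boolean ground truth


@dataclass
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8 RGB
    objects: list[SceneObject] = field(default_factory=list)

    @property
    def annotated(self) -> AnnotatedImage:
        h, w = self.image.shape[:2]
        return AnnotatedImage(
            image_id="scene",
            width=w,
            height=h,
            boxes=[o.box for o in self.objects],
        )


def _soil_background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Smoothly varying blend of the soil palette plus brightness mottle."""
    h, w = cfg.height, cfg.width
    palette = np.array(cfg.soil_palette, dtype=float)
    fields = np.stack(
        [ndi.gaussian_filter(rng.normal(size=(h, w)), sigma=12) for _ in palette]
    )
    weights = np.exp(3.0 * fields)
    weights /= weights.sum(axis=0)
    img = np.tensordot(weights, palette, axes=(0, 0))
    mottle = 1.0 + 0.12 * ndi.gaussian_filter(rng.normal(size=(h, w)), sigma=3)
    return img * mottle[..., None]


def _plant_mask(
    cfg: SceneConfig, rng: np.random.Generator, center: tuple[float, float], radius: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Rosette: central disk plus elongated elliptical lobes fanning out.

    Returns the union mask and the list of parts (disk first, then lobes)
    so each leaf can be painted with its own hue.
    """
    shape = (cfg.height, cfg.width)
    cy, cx = center
    parts: list[np.ndarray] = []
    disk = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(cy, cx, 0.35 * radius, 0.35 * radius, shape=shape)
    disk[rr, cc] = True
    parts.append(disk)
    n_lobes = int(rng.integers(cfg.leaf_lobes[0], cfg.leaf_lobes[1] + 1))
    base_angle = rng.uniform(0, 2 * np.pi)
    for j in range(n_lobes):
        angle = base_angle + 2 * np.pi * j / n_lobes + rng.normal(0, 0.1)
        length = radius * rng.uniform(0.7, 1.1)
        half_w = max(length * rng.uniform(0.15, 0.22), 3.0)
        # leaves radiate from the disk edge: attached to the center through
        # the disk, not to each other
        lcy = cy + (0.3 * radius + 0.5 * length) * np.sin(angle)
        lcx = cx + (0.3 * radius + 0.5 * length) * np.cos(angle)
        lobe = np.zeros(shape, dtype=bool)
        rr, cc = draw_ellipse(lcy, lcx, half_w, length / 2, rotation=-angle, shape=shape)
        lobe[rr, cc] = True
        parts.append(lobe)
    mask = np.logical_or.reduce(parts)
    return mask, parts


def _paint_plant(
    hsv: np.ndarray, parts: list[np.ndarray], cfg: SceneConfig, rng: np.random.Generator
) -> None:
    """Fill the plant pixels with green foliage tones, in place.

    Each leaf lobe gets its own hue offset around the rosette's base hue —
    field foliage is never a single green, and the yellowest leaves are the
    first to leave the detection band as it narrows. The central disk (the
    youngest growth) sits at the yellow edge of the range, as rosette
    centers do. Hues are clipped one step inside plant_hue_range so
    quantization through the uint8 RGB round trip cannot push a pixel out
    of the configured range.
    """
    lo, hi = cfg.plant_hue_range
    base = rng.uniform(lo + 3, lo + 0.55 * (hi - lo))
    # lobes first, the central disk last so the rosette center stays visible
    # where leaf bases overlap it
    for k, part in [*enumerate(parts)][1:] + [(0, parts[0])]:
        n = int(part.sum())
        if n == 0:
            continue
        if k == 0:
            # central disk: young growth at the extreme yellow edge of the
            # range; it is the first structure lost when the band narrows
            # fully, which breaks the rosette apart
            hue = np.full(n, lo + 1.0)
        else:
            part_hue = base + rng.normal(0, 6.0)
            hue = np.clip(part_hue + rng.normal(0, 1.0, size=n), lo + 1, hi - 1)
        sat = np.clip(rng.normal(185, 18, size=n), 110, 250)
        val = np.clip(rng.normal(160, 20, size=n), 90, 230)
        hsv[part, 0] = hue
        hsv[part, 1] = sat
        hsv[part, 2] = val


def _apply_shadow(
    hsv: np.ndarray, mask: np.ndarray, cfg: SceneConfig, rng: np.random.Generator
) -> None:
    """Darken the foliage on one side of a random line through the rosette."""
    if cfg.shadow_strength <= 0 or rng.uniform() > 0.8:
        return
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    theta = rng.uniform(0, 2 * np.pi)
    side = (rows - cy) * np.sin(theta) + (cols - cx) * np.cos(theta) > 0
    idx = (rows[side], cols[side])
    hsv[..., 2][idx] = hsv[..., 2][idx] * (1.0 - cfg.shadow_strength)


def _add_stones(
    hsv: np.ndarray,
    plant_union: np.ndarray,
    plants: list[np.ndarray],
    cfg: SceneConfig,
    rng: np.random.Generator,
) -> None:
    """Bright, weakly saturated stone blobs; hue just inside the wide band.

    About half the stones are dropped next to a plant so that wide-band
    masks merge them with the foliage — the failure mode that motivates
    narrowing the hue range.
    """
    shape = hsv.shape[:2]
    n_candidates = 6
    for s in range(n_candidates):
        if rng.uniform() > cfg.stone_probability:
            continue
        if plants and s % 2 == 0:
            # drop the stone inside a plant's bounding box, between the leaf
            # lobes, so a box crop cannot exclude it
            plant = plants[int(rng.integers(len(plants)))]
            rows, cols = np.nonzero(plant)
            cy = rng.uniform(rows.min(), rows.max())
            cx = rng.uniform(cols.min(), cols.max())
        else:
            cy = rng.uniform(0, shape[0])
            cx = rng.uniform(0, shape[1])
        a = rng.uniform(4, 11)
        rr, cc = draw_ellipse(
            cy, cx, a, a * rng.uniform(0.6, 1.0), rotation=rng.uniform(0, np.pi), shape=shape
        )
        blob = np.zeros(shape, dtype=bool)
        blob[rr, cc] = True
        blob &= ~plant_union  # stones never overwrite foliage pixels
        n = int(blob.sum())
        if n == 0:
            continue
        # Hue ramps smoothly across the blob (lit vs shaded stone faces span
        # the warm end of the band), so narrowing shaves the stone off one
        # slice at a time instead of dropping it in a single step.
        rows_b, cols_b = np.nonzero(blob)
        direction = rng.uniform(0, 2 * np.pi)
        proj = rows_b * np.sin(direction) + cols_b * np.cos(direction)
        span = np.ptp(proj)
        t = (proj - proj.min()) / span if span > 0 else np.zeros(n)
        hsv[blob, 0] = 23.0 + 11.0 * t + rng.normal(0, 0.6, size=n)
        hsv[blob, 1] = np.clip(rng.normal(42, 8, size=n), 22, 70)
        hsv[blob, 2] = np.clip(rng.normal(212, 10, size=n), 185, 238)


def generate_scene(config: SceneConfig | None = None) -> SyntheticScene:
    """Render one scene; fully determined by ``config.seed``."""
    cfg = config or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    soil_rgb = _soil_background(cfg, rng)
    hsv = rgb_to_hsv(np.clip(soil_rgb, 0, 255).astype(np.uint8)).astype(np.float64)

    margin = 8
    min_gap = 6
    plants: list[np.ndarray] = []
    labels: list[str] = []
    union = np.zeros((cfg.height, cfg.width), dtype=bool)
    for _ in range(cfg.n_plants):
        placed = False
        for _attempt in range(60):
            radius = rng.uniform(0.09, 0.15) * min(cfg.width, cfg.height)
            cy = rng.uniform(margin + radius, cfg.height - margin - radius)
            cx = rng.uniform(margin + radius, cfg.width - margin - radius)
            mask, parts = _plant_mask(cfg, rng, (cy, cx), radius)
            grown = ndi.binary_dilation(mask, iterations=min_gap)
            if not (grown & union).any():
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place all plants; reduce n_plants or enlarge scene")
        plants.append(mask)
        labels.append("crop" if rng.uniform() < 0.5 else "weed")
        union |= mask
        _paint_plant(hsv, parts, cfg, rng)
        _apply_shadow(hsv, mask, cfg, rng)

    if cfg.stone_probability > 0:
        _add_stones(hsv, union, plants, cfg, rng)

    image = hsv_to_rgb(
        np.stack(
            [
                np.clip(hsv[..., 0], 0, 179),
                np.clip(hsv[..., 1], 0, 255),
                np.clip(hsv[..., 2], 0, 255),
            ],
            axis=-1,
        )
    )
    if cfg.noise_sigma > 0:
        noisy = image.astype(np.float64) + rng.normal(0, cfg.noise_sigma, size=image.shape)
        image = np.clip(np.round(noisy), 0, 255).astype(np.uint8)

    objects = []
    for mask, label in zip(plants, labels):
        rows, cols = np.nonzero(mask)
        box = LabeledBox(
            label,
            int(cols.min()),
            int(rows.min()),
            int(cols.max() + 1),
            int(rows.max() + 1),
        )
        objects.append(SceneObject(class_name=label, box=box, mask=mask))
    return SyntheticScene(image=image, objects=objects)


def generate_dataset(
    n_scenes: int,
    config: SceneConfig | None = None,
    out_dir: str | Path | None = None,
) -> list[SyntheticScene]:
    """Generate ``n_scenes`` scenes with per-scene seeds derived from the
    master seed; optionally write images, VOC XML and reference masks.

    Layout under ``out_dir``: ``images/scene_NNNN.png``,
    ``annotations/scene_NNNN.xml``, ``masks/scene_NNNN_objMM.png``.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    cfg = config or SceneConfig()
    scenes = []
    for i in range(n_scenes):
        scene_cfg = replace(cfg, seed=(cfg.seed * 100003 + i) % (2**31))
        scenes.append(generate_scene(scene_cfg))

    if out_dir is not None:
        out = Path(out_dir)
        for sub in ("images", "annotations", "masks"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        for i, scene in enumerate(scenes):
            stem = f"scene_{i:04d}"
            Image.fromarray(scene.image).save(out / "images" / f"{stem}.png")
            annotated = scene.annotated
            annotated.image_id = stem
            write_voc_annotation(annotated, out / "annotations" / f"{stem}.xml")
            for j, obj in enumerate(scene.objects):
                mask_img = (obj.mask.astype(np.uint8)) * 255
                Image.fromarray(mask_img).save(out / "masks" / f"{stem}_obj{j:02d}.png")
    return scenes
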