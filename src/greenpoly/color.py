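"""HSV color segmentation primitives.

Hue is kept on the byte convention used throughout agricultural CV work:
H in 0-179 (half-degrees), S and V in 0-255. Green vegetation then falls
roughly in H 35-85, which is what the iterative annotator exploits.

Binary masks are plain 2-D boolean arrays in crop-local coordinates
(row = y, col = x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

__all__ = [
    "HsvBand",
    "Contour",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "hue_band_mask",
    "refine_mask",
    "largest_contour",
]

_KERNEL_3X3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class HsvBand:
    """Closed per-channel bounds; a pixel passes iff inside all three."""

    h_low: int
    h_high: int
    s_low: int = 20
    s_high: int = 255
    v_low: int = 20
    v_high: int = 240

    def __post_init__(self) -> None:
        if not (0 <= self.h_low <= self.h_high <= 179):
            raise ValueError(f"bad hue bounds [{self.h_low}, {self.h_high}]")
        for lo, hi, name in (
            (self.s_low, self.s_high, "saturation"),
            (self.v_low, self.v_high, "value"),
        ):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"bad {name} bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class Contour:
    """Principal connected component of a binary mask.

    ``points`` is the traced outer boundary as an ``(N, 2)`` float array of
    ``(x, y)`` crop-local coordinates (closed: last point equals the first).
    ``area`` is the component's pixel count, ``rect`` its tight pixel
    bounding box ``(x, y, w, h)``, ``perimeter`` the arc length of the
    traced boundary.
    """

    points: np.ndarray
    area: float
    rect: tuple[int, int, int, int]
    perimeter: float


def rgb_to_hsv(crop: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to HSV with H 0-179, S/V 0-255 (uint8)."""
    if crop.ndim != 3 or crop.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB input, got shape {crop.shape}")
    rgb = crop.astype(np.float64) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = rgb.max(axis=-1)
    delta = v - rgb.min(axis=-1)
    s = np.where(v > 0, delta / np.where(v > 0, v, 1.0), 0.0)

    h = np.zeros_like(v)
    nz = delta > 0
    dn = np.where(nz, delta, 1.0)
    rmax = nz & (v == r)
    gmax = nz & ~rmax & (v == g)
    bmax = nz & ~rmax & ~gmax
    h[rmax] = ((g - b) / dn)[rmax] % 6.0
    h[gmax] = ((b - r) / dn)[gmax] + 2.0
    h[bmax] = ((r - g) / dn)[bmax] + 4.0
    h *= 30.0  # 60 deg per sextant, halved to the 0-179 scale

    out = np.empty_like(crop, dtype=np.uint8)
    out[..., 0] = np.round(h).astype(np.int64) % 180
    out[..., 1] = np.round(s * 255.0).astype(np.uint8)
    out[..., 2] = np.round(v * 255.0).astype(np.uint8)
    return out


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv` (uint8 in, uint8 out)."""
    h = hsv[..., 0].astype(np.float64) / 30.0  # sextant index, 0-6
    s = hsv[..., 1].astype(np.float64) / 255.0
    v = hsv[..., 2].astype(np.float64) / 255.0
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    rgb = np.stack([r, g, b], axis=-1)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def hue_band_mask(hsv: np.ndarray, band: HsvBand) -> np.ndarray:
    """Boolean mask of pixels whose H, S, V all lie in the band's bounds."""
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    return (
        (h >= band.h_low)
        & (h <= band.h_high)
        & (s >= band.s_low)
        & (s <= band.s_high)
        & (v >= band.v_low)
        & (v <= band.v_high)
    )


def refine_mask(mask: np.ndarray, close_iter: int = 2, open_iter: int = 1) -> np.ndarray:
    """Morphological closing then opening with a 3x3 square element.

    Closing (2 iterations) restores connectivity and fills pinholes;
    opening (1 iteration) removes speckle. Border pixels are treated as the
    identity of each operation (erosion sees foreground outside the image,
    dilation sees background), so an all-foreground mask passes unchanged.
    """
    m = mask.astype(bool)
    if close_iter > 0:
        m = ndi.binary_dilation(m, _KERNEL_3X3, iterations=close_iter, border_value=0)
        m = ndi.binary_erosion(m, _KERNEL_3X3, iterations=close_iter, border_value=1)
    if open_iter > 0:
        m = ndi.binary_erosion(m, _KERNEL_3X3, iterations=open_iter, border_value=1)
        m = ndi.binary_dilation(m, _KERNEL_3X3, iterations=open_iter, border_value=0)
    return m


def _trace_boundary(component: np.ndarray) -> np.ndarray:
    """Outer boundary of a single component as closed (x, y) points."""
    padded = np.pad(component, 1, mode="constant")
    contours = measure.find_contours(padded.astype(float), 0.5)
    # outermost boundary = the longest closed curve
    boundary = max(contours, key=len)
    pts = boundary[:, ::-1] - 1.0  # (row, col) -> (x, y), undo padding
    return pts


def largest_contour(mask: np.ndarray, min_area: float = 0.0) -> Contour | None:
    """Principal contour of a mask: the connected component of maximal area.

    Components are 8-connected; area is the pixel count; ties are broken by
    label order (row-major scan order of first pixels). Returns ``None`` if
    the mask is empty or the largest component is below ``min_area``.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    labels, n = ndi.label(mask, structure=_KERNEL_3X3)
    if n == 0:
        return None
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(areas))  # first maximum in scan order
    area = float(areas[best])
    if area < min_area:
        return None
    component = labels == best + 1
    rows, cols = np.nonzero(component)
    rect = (
        int(cols.min()),
        int(rows.min()),
        int(cols.max() - cols.min() + 1),
        int(rows.max() - rows.min() + 1),
    )
    points = _trace_boundary(component)
    perimeter = float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))
    return Contour(points=points, area=area, rect=rect, perimeter=perimeter)
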