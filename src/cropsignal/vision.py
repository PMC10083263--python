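"""Plant/soil segmentation and connected-component extraction.

Plants (crop and weeds alike) are separated from the soil background by
a per-pixel HSV interval rule: a pixel is foreground iff hue, saturation
and value each lie inside a closed ``[low, high]`` band.  The default
bands — hue in [10, 120] on the 0..179 halved-degree scale, saturation
and value in [10, 255] — accept green plant matter under controlled
illumination and reject soil.  The binary mask is then cleaned by a
morphological opening (erosion then dilation with a 3x3 square element)
to drop speckle noise, and maximal 8-connected foreground regions are
extracted as plant candidates with contour, centroid, bounding box and
area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "HsvThresholds",
    "PlantComponent",
    "rgb_to_hsv",
    "segment",
    "open_mask",
    "extract_components",
]

_SQUARE_3X3 = np.ones((3, 3), dtype=bool)
_CROSS_3X3 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class HsvThresholds:
    """Closed acceptance bands per HSV channel.

    Hue is on the 8-bit halved-degree scale (0..179); saturation and
    value on 0..255.  With ``full_degrees=True`` the hue band is
    interpreted on 0..359 instead and halved internally.
    """

    h_low: int = 10
    h_high: int = 120
    s_low: int = 10
    s_high: int = 255
    v_low: int = 10
    v_high: int = 255
    full_degrees: bool = False

    def __post_init__(self):
        for name in ("h", "s", "v"):
            lo, hi = getattr(self, f"{name}_low"), getattr(self, f"{name}_high")
            if lo > hi:
                raise ValueError(f"{name}_low ({lo}) must be <= {name}_high ({hi})")

    @property
    def hue_band(self) -> tuple[float, float]:
        """Hue band on the 0..179 halved-degree scale."""
        if self.full_degrees:
            return (self.h_low / 2.0, self.h_high / 2.0)
        return (float(self.h_low), float(self.h_high))


@dataclass(frozen=True)
class PlantComponent:
    """One maximal 8-connected foreground region (a plant candidate).

    ``pixels`` and ``contour`` are ``(n, 2)`` integer arrays of
    ``(row, col)`` coordinates in row-major order; contour pixels are
    members of the region with at least one background 4-neighbor or
    lying on the image edge.  ``centroid`` is the unweighted pixel mean
    as ``(x, y)`` = (mean col, mean row).
    """

    pixels: np.ndarray
    contour: np.ndarray
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) inclusive
    area: int


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to 8-bit HSV.

    Standard hexcone conversion with hue reported in halved degrees
    (0..179) so the whole triplet fits in uint8: pure red maps to hue 0,
    pure green (120 deg) to 60.  Saturation and value are scaled to
    0..255.  Achromatic pixels get hue 0 and saturation 0.
    """
    rgb = np.asarray(image)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {rgb.shape}")
    r, g, b = (rgb[..., i].astype(np.float64) for i in range(3))
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc

    hue = np.zeros_like(maxc)
    nz = delta > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rc = np.where(nz, (maxc - r) / delta, 0.0)
        gc = np.where(nz, (maxc - g) / delta, 0.0)
        bc = np.where(nz, (maxc - b) / delta, 0.0)
    hue = np.where(maxc == r, bc - gc, hue)
    hue = np.where(maxc == g, 2.0 + rc - bc, hue)
    hue = np.where((maxc == b) & (maxc != r) & (maxc != g), 4.0 + gc - rc, hue)
    hue = np.where(nz, (hue % 6.0) * 30.0, 0.0)  # 60 deg sector / 2

    sat = np.zeros_like(maxc)
    vz = maxc > 0
    sat[vz] = delta[vz] / maxc[vz] * 255.0

    out = np.empty(rgb.shape, dtype=np.uint8)
    out[..., 0] = np.floor(hue + 0.5).astype(np.uint8) % 180
    out[..., 1] = np.floor(sat + 0.5).astype(np.uint8)
    out[..., 2] = maxc.astype(np.uint8)
    return out


def segment(hsv: np.ndarray, thresholds: HsvThresholds | None = None) -> np.ndarray:
    """Threshold an HSV image into a {0, 255} plant mask.

    A pixel is foreground (255) iff hue, saturation and value each lie
    inside their closed acceptance band; otherwise background (0).
    """
    if thresholds is None:
        thresholds = HsvThresholds()
    hsv = np.asarray(hsv)
    h = hsv[..., 0].astype(np.float64)
    s = hsv[..., 1]
    v = hsv[..., 2]
    h_lo, h_hi = thresholds.hue_band
    keep = (
        (h >= h_lo)
        & (h <= h_hi)
        & (s >= thresholds.s_low)
        & (s <= thresholds.s_high)
        & (v >= thresholds.v_low)
        & (v <= thresholds.v_high)
    )
    return np.where(keep, 255, 0).astype(np.uint8)


def open_mask(mask: np.ndarray) -> np.ndarray:
    """Morphological opening with a 3x3 square structuring element.

    One erosion followed by one dilation with the same element; pixels
    outside the frame count as background, so foreground touching the
    border is eroded there too.  Removes isolated speckle while
    preserving regions at least as large as the element.
    """
    fg = np.asarray(mask) > 0
    eroded = ndimage.binary_erosion(fg, structure=_SQUARE_3X3, border_value=0)
    opened = ndimage.binary_dilation(eroded, structure=_SQUARE_3X3, border_value=0)
    return np.where(opened, 255, 0).astype(np.uint8)


def extract_components(mask: np.ndarray) -> list[PlantComponent]:
    """Extract all maximal 8-connected foreground regions.

    Returns components ordered by descending area, ties broken by the
    row-major-first (top-left-most) pixel.  Contours are the region
    pixels with at least one background 4-neighbor or on the image edge;
    interior holes therefore contribute their own boundary ring.
    """
    fg = np.asarray(mask) > 0
    labels, n = ndimage.label(fg, structure=_SQUARE_3X3)  # 8-connectivity
    if n == 0:
        return []
    # Interior = pixels whose full 4-neighborhood is foreground (same component).
    interior = ndimage.binary_erosion(fg, structure=_CROSS_3X3, border_value=0)
    boundary = fg & ~interior

    comps: list[PlantComponent] = []
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        sub = labels[sl] == lab
        rr, cc = np.nonzero(sub)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        pixels = np.column_stack([rows, cols])
        on_boundary = boundary[rows, cols]
        contour = pixels[on_boundary]
        comps.append(
            PlantComponent(
                pixels=pixels,
                contour=contour,
                centroid=(float(cols.mean()), float(rows.mean())),
                bbox=(int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())),
                area=int(pixels.shape[0]),
            )
        )
    comps.sort(key=lambda c: (-c.area, c.pixels[0, 0], c.pixels[0, 1]))
    return comps
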